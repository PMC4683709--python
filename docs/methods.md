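# Methods

## Problem and model

Spliceosomal introns are gained rarely and lost recurrently. Three
mechanisms are commonly proposed for loss. Under **reverse transcription**
(mRNA-mediated loss), recombination between genomic DNA and cDNA reverse
transcribed from spliced mRNA removes introns precisely; because reverse
transcription frequently aborts, partial cDNAs anchored at the 3′ end
produce a 3′ positional bias and simultaneous loss of adjacent introns, and
if the recombination is a gene conversion, its G/C-favouring repair bias
leaves locally elevated GC in the flanking exons. **Genomic deletion**
removes an intron with no positional bias and typically scars the flanking
exons with small indels (an imprecise loss). **NHEJ repair** of double-
strand breaks uses microhomology, predicting short direct repeats at the
boundaries of lost introns. The package turns each prediction into a
measurable site feature and a test.

Intron positions are compared at codon-offset + phase resolution across
one-to-one orthologs. Presence/absence profiles over a fixed rooted species
tree are reconstructed by **Dollo parsimony**: a character may be gained at
most once, so the origin is the MRCA of the tips carrying the intron and
the minimal loss set is the set of maximal subtrees below the origin whose
tips are all absent or unknown and contain at least one confirmed absence.
This greedy construction is provably minimal on a tree and is additionally
verified in the tests against exhaustive minimization over all internal
assignments for every possible five-tip profile, including profiles with
unknowns.

## Coordinates and projection

Internally all genomic intervals are 0-based half-open; GFF3 I/O converts
to/from 1-based inclusive. A gene model is one transcript's spliced CDS
(the longest CDS when several are annotated); UTRs are ignored, so the
"relative position" of an intron is upstream spliced-CDS length divided by
total CDS length. This choice (CDS, not full mRNA) is made explicit because
annotation of UTRs is typically absent or unreliable in compact genomes.

One species (DDB by default) anchors the coordinate system: every other
species is aligned pairwise to its anchor ortholog, and a site key is the
anchor-CDS offset reached by consuming the intron's own ungapped offset
through the alignment, together with the intron's phase. A boundary that
abuts a gap run maps to the column before the gaps (the minimal column).
Protein alignment uses the global affine-gap aligner from Biopython
(BLOSUM62, gap open 10, extend 0.5) expanded to codons; its score is
checked against an independent scalar Gotoh DP in the tests, and the
traceback used is the aligner's canonical first optimal path, which is
deterministic. External alignments can be substituted; with a single
aligner the site set is produced in single-aligner mode (the original
two-aligner consensus is approximated by accepting the built-in alignment
and, when supplied, requiring agreement with an external one).

States at a site: *present* (intron at that column and phase), *absent*
(aligned with flank similarity ≥ 0.5 and no intron), *unknown* (no
ortholog, or an unalignable neighbourhood). Flank similarity is the
fraction of identical non-gap column pairs over 45 aligned-CDS columns per
side (gaps and N count as mismatch; truncated windows use the available
column count as denominator). A low-quality neighbourhood in the focal-pair
alignment discards the site, matching the original filter, which was
defined on the similarity between the two focal species (the 0.5 threshold
is that analysis's first quartile of whole-alignment similarities; the
package recomputes a dataset's Q1 — type-7 linear interpolation — so the
threshold can be re-derived). In an outgroup pair a low-quality
neighbourhood only demotes that outgroup to unknown: unknowns never force
losses but block the strict gain criterion, which demands confirmed absence
in every other taxon. A site whose last confirmed intron is demoted this
way carries no information and is dropped. When junction data are supplied,
an extant intron at a discordant position must be matched exactly (both
splice sites, ≥ 1 read) by a junction or the site is discarded; with no
junction data sites are retained unchanged, since absence of evidence is
not evidence against.

Ancestral intron ordinals — required by the adjacency statistics, whose
convention is that three consecutive lost introns form two pairs — are
assigned per gene as the rank of the site's anchor offset among sites
present in more than one species (single-presence sites are gain candidates
and excluded from the numbering). This equals the ancestral ordinal
whenever every ancestral intron survives in at least one lineage; an intron
lost in all five species is undetectable by any comparative method.

## Statistics

* **Resampling null**: draw `n_lost` introns uniformly without replacement
  from the pool of lost + extant introns, count adjacent pairs, repeat R
  (default 10,000) times; p = tail/R, so a never-exceeded observation
  reports p = 0, with the shrunk (tail+1)/(R+1) estimate logged alongside.
* **Exact independence null**: per gene, the distribution of adjacent-pair
  counts when k of n ordinals are chosen uniformly at random, computed by a
  DP over the ordinal path with state (chosen so far, last position
  chosen); the clade-wide distribution is the convolution across genes,
  conditioned on the observed per-gene loss counts. The DP equals subset
  enumeration exhaustively for all n ≤ 8 in the tests. Note the two nulls
  condition differently (the resampling redistributes losses across genes);
  they coincide on a single-gene pool, which is the fixture used for the
  Monte-Carlo convergence check.
* Classical tests delegate to scipy: Pearson 2×2 chi-square without
  continuity correction by default (a flag enables Yates), with a zero
  margin returning χ² = 0, p = 1 and a warning; Mann–Whitney U exact for
  tie-free samples with min(n, m) ≤ 8, otherwise tie-corrected normal
  approximation with continuity correction; Wilcoxon signed rank against a
  median of 0.5 with zeros dropped, exact up to n = 25.
* Precision: a loss is precise iff no gap column lies within 15 aligned-CDS
  columns on either side of the lost position. The window size is not
  dictated by the underlying definition ("no indel in the flanking exonic
  sequences"); 15 columns is this package's default and is configurable.
* GC: flank windows use spliced (exonic) sequence only and never reach into
  neighbouring introns; pooled two-side GC is the primary statistic, per-
  side values are kept for diagnostics; N bases count as non-GC and leave
  the denominator. Relative GC divides by the median flank GC at the same
  gene's conserved introns (middle element / mean of the two middle).
  4-fold GC trims windows to whole codons of the reading frame and uses
  third positions of the eight 4-fold codon families.
* For a lost intron, ordinal, length, boundary sequences and relative
  position are taken from the intron-bearing ortholog (the intron no longer
  exists in the focal species); flank GC and relative GC are measured in
  the focal (intron-lost) species, where the conversion signature resides.

## Synthetic clade generator

The generator emulates the statistical structure the analysis assumes, not
any real genome's composition. Ancestral genes are random CDSs (AT-rich
codons, ~120–400 aa) with 1–12 introns at 5′-biased positions (Beta(1,
1.3)), intron lengths log-normal with median ≈ 100 bp and canonical GT..AG
boundaries. Per-branch events are planted with recorded ground truth:

* RT losses draw a 3′ anchor (exponential, mean 0.3 of gene length from the
  3′ end), remove an intron 3′ of it — or, with probability 0.2, the whole
  adjacent run — precisely, and raise flank GC by 0.08 over the 100-bp
  windows via third-codon A→G/T→C flips;
* genomic deletions remove the intron plus 3 or 6 bp of flanking exon.
  Frame-breaking indels are not planted: a frameshifted gene would be
  discarded by the annotation-error filter and silently leave the ortholog
  set, which is also why coding substitutions that would create an in-frame
  stop are rejected (purifying selection, in effect);
* NHEJ losses copy the intron's first 2–6 bases onto the downstream exon in
  the *ancestor* (microhomology is ancestral), then remove precisely;
* gains copy a recorded slice of another gene's intron, wrap it in GT..AG
  and insert it in one species; a configurable fraction (default 0.5) gets
  a detectable source hit in the emitted gain-hit table, alongside a
  self-hit and a weak decoy that must be rejected.

Default scale is 300 genes with 55/25 losses and 5/8 gains on the two focal
terminals — the loss fractions (~2.8% and ~1.1% of the intron pool) and the
overwhelmingly precise mechanism mix mirror the real clade at desk scale.
Substitutions are uniform per branch (2% focal terminals, 5–9% outgroups);
no indels occur outside planted ones, so alignment ambiguity cannot
confound the precision classifier in tests. Parallel loss of the same
intron in both focal species is excluded by the planner so that every
planted loss is a terminal-branch event under Dollo. RBH hit tables and
gain-source hit tables are synthesized from the simulator's own ortholog
knowledge with controlled fields rather than run through an aligner, so the
threshold logic is exercised deterministically.

What passing on synthetic clades does **not** show: robustness to
annotation errors beyond the modelled ones, to paralogy and gene family
turnover (RBH tables are ideal), to alignment ambiguity from real indel
processes, or to non-uniform substitution processes. Those failure modes
must be assessed on real data.

## Numerical and design choices

* Thresholds default to the values of the source analysis: RBH E ≤ 1e-10,
  identity ≥ 25%; flank window 45 columns, similarity ≥ 0.5; gain-source
  E ≤ 1e-10, coverage ≥ 0.80 (query = intron coverage), similarity ≥ 0.85;
  GC window 100 bp (50/200 available); R = 10,000.
* "Similarity" for gain-source hits is fraction identity over the aligned
  region, the only similarity available in tabular BLAST output; a self-hit
  is any hit overlapping the intron's own locus by ≥ 1 bp.
* Best-hit ties break to lower e-value, then higher identity, then
  lexicographic subject id, with an ambiguity warning.
* Problem sizes in the test-suite and acceptance runs (300-gene clades, 100
  + 40 planted losses, R = 2,000 resampling, 200-dataset type-I check) are
  chosen so each property is measured with comfortable statistical margin
  at interactive runtimes; all sizes scale up by configuration.
* The independence-null probability printed for the real clade (0.0027)
  depends on the real per-gene loss placement and cannot be recomputed
  without those data; the package implements the stated assumption —
  uniform loss placement within genes, convolved across genes — and
  validates it exhaustively at small n instead.
* The 45-bp similarity window is interpreted as aligned-CDS columns (a
  fraction over a fixed window, gaps as mismatches); whether the original
  was computed on nucleotide or aligned-codon coordinates is not stated,
  and both interpretations can be obtained by supplying the window size.

## Known limitations

Single-anchor projection means sites unalignable against the anchor are
invisible even if alignable between other species pairs. Dollo parsimony
cannot see parallel losses of the same site on both focal terminals (they
reconstruct as one internal-branch loss). The junction filter requires
exact splice-site matches and does not model alternative splicing. The
gain-source search consumes precomputed hit tables; it does not run BLAST.
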