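"""Synthetic five-taxon clade with known intron loss/gain histories.

The generator builds an ancestral set of multi-exon genes, evolves one copy
per species along the fixed topology ((((DDB,DPU),PPA),DFA),EHI), and plants
loss and gain events with recorded ground truth, so that every pipeline stage
can be exercised — and its calls scored — without any genome download.

Loss mechanisms follow the three classical models:

* ``reverse_transcription`` — a partial cDNA anchors at a random distance
  from the 3' end (exponential; scale = ``rt_3prime_bias``) and recombination
  removes introns 3' of the anchor, precisely; with probability
  ``rt_coloss_prob`` a whole run of adjacent introns goes at once. Flank GC
  is raised by ``gc_elevation_at_loss`` (biased gene conversion signature).
* ``genomic_deletion`` — the intron plus 3 or 6 bp of flanking exon are
  deleted (frame-preserving, so the gene still passes annotation checks).
* ``nhej`` — a short direct repeat (2-6 bp) is planted at the intron
  boundary in the ancestor, then the intron is removed precisely.

Substitutions are uniform (Jukes-Cantor-like); proposals that would create an
in-frame stop codon, or touch the GT..AG intron boundaries, are rejected —
otherwise affected genes would be discarded as annotation errors and silently
vanish from the ortholog set. GC elevation likewise only flips third-codon
A->G / T->C, which cannot create a stop.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

SPECIES = ("DDB", "DPU", "PPA", "DFA", "EHI")
STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ATGC"))
#: AT-rich composition loosely mimicking slime-mold coding sequence
_BASE_P = np.array([0.32, 0.32, 0.18, 0.18])


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions at desk scale.

    Loss counts and gain counts are per terminal branch; the default loss
    fractions (~2.8% of the intron pool in DDB, ~1.1% in DPU) and mechanism
    mix (losses overwhelmingly precise) mirror the rates observed in the real
    clade, scaled to a few hundred genes.
    """

    seed: int = 0
    n_genes: int = 300
    introns_per_gene: tuple[int, int] = (1, 12)  # uniform inclusive
    intron_len_log_mu: float = 4.605  # median ~100 bp
    intron_len_log_sigma: float = 0.35
    intron_len_min: int = 15
    protein_len_range: tuple[int, int] = (120, 400)
    loss_counts: dict = field(default_factory=lambda: {"DDB": 55, "DPU": 25})
    mechanism_mix: dict = field(
        default_factory=lambda: {"reverse_transcription": 0.99, "genomic_deletion": 0.01, "nhej": 0.0}
    )
    rt_3prime_bias: float = 0.3  # mean anchor distance from the 3' end (fraction)
    rt_coloss_prob: float = 0.2
    gc_elevation_at_loss: float = 0.08  # additive GC shift in 100-bp flanks
    gc_window: int = 100
    gain_counts: dict = field(default_factory=lambda: {"DDB": 5, "DPU": 8})
    gain_source_detectable_frac: float = 0.5
    substitution_rates: dict = field(
        default_factory=lambda: {"DDB": 0.02, "DPU": 0.02, "PPA": 0.05, "DFA": 0.07, "EHI": 0.09}
    )
    minus_strand_frac: float = 0.3

    def __post_init__(self) -> None:
        total = sum(self.mechanism_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mechanism fractions must sum to 1")
        if any(v < 0 for v in self.mechanism_mix.values()):
            raise ValueError("mechanism fractions must be non-negative")

    @property
    def run_id(self) -> str:
        return f"sim-{self.seed}"


@dataclass
class SimIntron:
    anc_ordinal: int
    seq: str


@dataclass
class SimGene:
    """One gene of one lineage: exon sequences and the introns between them."""

    anc_id: str
    strand: str
    exons: list[str]
    introns: list[SimIntron]

    @property
    def spliced_cds(self) -> str:
        return "".join(self.exons)

    def intron_offsets(self) -> list[int]:
        offs, acc = [], 0
        for exon in self.exons[:-1]:
            acc += len(exon)
            offs.append(acc)
        return offs

    def copy(self) -> "SimGene":
        return SimGene(
            self.anc_id,
            self.strand,
            list(self.exons),
            [SimIntron(i.anc_ordinal, i.seq) for i in self.introns],
        )


@dataclass
class TruthRecord:
    species: str
    gene: str  # ancestral gene id
    event: str  # loss | gain
    anc_ordinal: int  # for gains: 0
    mechanism: str
    precise: bool
    flank_indel_bp: int
    planted_repeat: int
    anc_offset: int
    gain_source: str = ""
    intron_id: str = ""


@dataclass
class SimTruth:
    run_id: str
    records: list[TruthRecord]
    n_ancestral_introns: dict = field(default_factory=dict)  # gene -> count

    def losses(self, species: str | None = None) -> list[TruthRecord]:
        return [
            r
            for r in self.records
            if r.event == "loss" and (species is None or r.species == species)
        ]

    def gains(self, species: str | None = None) -> list[TruthRecord]:
        return [
            r
            for r in self.records
            if r.event == "gain" and (species is None or r.species == species)
        ]


# ---------------------------------------------------------------- ancestor


def _random_codon(rng) -> str:
    while True:
        codon = "".join(rng.choice(_BASES, size=3, p=_BASE_P))
        if codon not in STOPS:
            return codon


def _random_cds(n_aa: int, rng) -> str:
    return "ATG" + "".join(_random_codon(rng) for _ in range(n_aa - 1)) + "TAA"


def _random_intron(length: int, rng) -> str:
    interior = "".join(rng.choice(_BASES, size=length - 4, p=np.array([0.37, 0.37, 0.13, 0.13])))
    return "GT" + interior + "AG"


def build_ancestor(cfg: SimulationConfig, rng) -> list[SimGene]:
    """Ancestral gene set: random CDS split by introns at 5'-biased positions."""
    genes = []
    lo, hi = cfg.introns_per_gene
    for idx in range(cfg.n_genes):
        n_aa = int(rng.integers(*cfg.protein_len_range))
        cds = _random_cds(n_aa, rng)
        max_introns = max(1, (len(cds) - 6) // 15)
        n_introns = min(int(rng.integers(lo, hi + 1)), max_introns)
        offsets: list[int] = []
        tries = 0
        while len(offsets) < n_introns and tries < 200:
            tries += 1
            off = 3 + int(rng.beta(1.0, 1.3) * (len(cds) - 6))
            if all(abs(off - o) >= 12 for o in offsets):
                offsets.append(off)
        offsets.sort()
        exons, prev = [], 0
        for off in offsets:
            exons.append(cds[prev:off])
            prev = off
        exons.append(cds[prev:])
        introns = []
        for j in range(len(offsets)):
            length = max(
                cfg.intron_len_min,
                int(rng.lognormal(cfg.intron_len_log_mu, cfg.intron_len_log_sigma)),
            )
            introns.append(SimIntron(j + 1, _random_intron(length, rng)))
        strand = "-" if rng.random() < cfg.minus_strand_frac else "+"
        genes.append(SimGene(f"g{idx:04d}", strand, exons, introns))
    return genes


# ------------------------------------------------------------- mutation ops


def _codon_has_stop(cds: str, pos: int) -> bool:
    start = pos - pos % 3
    return cds[start : start + 3] in STOPS


def substitute_gene(gene: SimGene, rate: float, rng) -> None:
    """Apply uniform substitutions in place; CDS proposals creating a stop
    codon are rejected and intron GT..AG boundaries are preserved."""
    if rate <= 0:
        return
    cds = list(gene.spliced_cds)
    n = rng.binomial(len(cds), rate)
    for pos in rng.choice(len(cds), size=n, replace=False) if n else []:
        old = cds[pos]
        new = str(rng.choice([b for b in "ACGT" if b != old]))
        cds[pos] = new
        if _codon_has_stop("".join(cds[pos - pos % 3 : pos - pos % 3 + 3]), 0):
            cds[pos] = old
    _resplit(gene, "".join(cds))
    for intr in gene.introns:
        seq = list(intr.seq)
        m = rng.binomial(max(len(seq) - 4, 0), rate)
        if m and len(seq) > 4:
            for pos in rng.choice(np.arange(2, len(seq) - 2), size=m, replace=False):
                seq[pos] = str(rng.choice([b for b in "ACGT" if b != seq[pos]]))
            intr.seq = "".join(seq)


def _resplit(gene: SimGene, cds: str) -> None:
    exons, prev = [], 0
    for exon in gene.exons:
        exons.append(cds[prev : prev + len(exon)])
        prev += len(exon)
    gene.exons = exons


def elevate_flank_gc(gene: SimGene, offset: int, window: int, shift: float, rng) -> None:
    """Raise spliced-CDS GC around ``offset`` by ~``shift`` via third-codon
    A->G / T->C flips (cannot create a stop codon)."""
    cds = gene.spliced_cds
    lo, hi = max(offset - window, 0), min(offset + window, len(cds))
    eligible = [i for i in range(lo, hi) if i % 3 == 2 and cds[i] in "AT"]
    if not eligible:
        return
    p = min(1.0, shift * (hi - lo) / len(eligible))
    s = list(cds)
    for i in eligible:
        if rng.random() < p:
            s[i] = "G" if s[i] == "A" else "C"
    _resplit(gene, "".join(s))


def remove_intron(gene: SimGene, idx: int, exon_deletion: int = 0, rng=None) -> bool:
    """Remove intron ``idx``; optionally delete ``exon_deletion`` flanking
    exonic bases (split between the two sides at random). Returns False
    without modifying the gene if the deletion would create a stop codon."""
    up, down = gene.exons[idx], gene.exons[idx + 1]
    if exon_deletion:
        left = int(rng.integers(0, exon_deletion + 1))
        right = exon_deletion - left
        if left > len(up) - 3 or right > len(down) - 3:
            return False
        up2 = up[: len(up) - left]
        down2 = down[right:]
    else:
        up2, down2 = up, down
    merged = up2 + down2
    new_exons = gene.exons[:idx] + [merged] + gene.exons[idx + 2 :]
    cds = "".join(new_exons)
    if len(cds) % 3 != 0:
        return False
    for i in range(0, len(cds) - 3, 3):  # interior stop check
        if cds[i : i + 3] in STOPS:
            return False
    gene.exons = new_exons
    gene.introns = gene.introns[:idx] + gene.introns[idx + 1 :]
    return True


def plant_repeat(gene: SimGene, idx: int, r: int) -> bool:
    """Plant a 5' direct repeat: the first ``r`` intron bases are copied onto
    the start of the downstream exon (in the ancestor, so every descendant
    carries the microhomology). Rejected if it would create a stop codon."""
    intron = gene.introns[idx].seq
    down = gene.exons[idx + 1]
    if r > min(len(intron), len(down) - 3):
        return False
    new_down = intron[:r] + down[r:]
    exons = gene.exons[: idx + 1] + [new_down] + gene.exons[idx + 2 :]
    cds = "".join(exons)
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3] in STOPS:
            return False
    gene.exons = exons
    return True


# ------------------------------------------------------------ event planner


@dataclass
class _PlannedLoss:
    species: str
    gene: str
    anc_ordinal: int
    mechanism: str
    exon_deletion: int = 0
    planted_repeat: int = 0


def plan_losses(cfg: SimulationConfig, ancestor: list[SimGene], rng) -> list[_PlannedLoss]:
    """Choose (species, gene, ordinal, mechanism) for every requested loss.

    Introns already lost in the other focal lineage are excluded so that
    every planted loss maps to a terminal branch under Dollo parsimony.
    """
    relpos: dict[str, list[float]] = {}
    for g in ancestor:
        L = len(g.spliced_cds)
        relpos[g.anc_id] = [off / L for off in g.intron_offsets()]
    taken: set[tuple[str, int]] = set()  # lost in any species
    plans: list[_PlannedLoss] = []
    mechs = list(cfg.mechanism_mix)
    probs = np.array([cfg.mechanism_mix[m] for m in mechs])
    for species, target in cfg.loss_counts.items():
        avail: dict[str, set[int]] = {
            g.anc_id: {i.anc_ordinal for i in g.introns} for g in ancestor
        }
        for gid, ords in avail.items():
            ords -= {o for (gg, o) in taken if gg == gid}
        planted = 0
        guard = 0
        while planted < target:
            guard += 1
            if guard > 100_000:
                raise RuntimeError("more losses requested than available introns")
            mech = mechs[int(rng.choice(len(mechs), p=probs))]
            gene_ids = [gid for gid, s in avail.items() if s]
            if not gene_ids:
                raise ValueError("more losses requested than available introns")
            gid = gene_ids[int(rng.integers(len(gene_ids)))]
            ords = sorted(avail[gid])
            if mech == "reverse_transcription":
                anchor = 1.0 - min(rng.exponential(cfg.rt_3prime_bias), 1.0)
                cand = [o for o in ords if relpos[gid][o - 1] >= anchor]
                if not cand:
                    cand = [ords[-1]]
                if len(cand) > 1 and rng.random() < cfg.rt_coloss_prob:
                    run = [cand[-1]]
                    for o in reversed(cand[:-1]):
                        if o == run[-1] - 1:
                            run.append(o)
                        else:
                            break
                    chosen = sorted(run)[: max(target - planted, 1)]
                else:
                    chosen = [cand[int(rng.integers(len(cand)))]]
                for o in chosen:
                    plans.append(_PlannedLoss(species, gid, o, mech))
            elif mech == "genomic_deletion":
                o = ords[int(rng.integers(len(ords)))]
                indel = int(rng.choice([3, 6]))
                plans.append(_PlannedLoss(species, gid, o, mech, exon_deletion=indel))
                chosen = [o]
            else:  # nhej
                o = ords[int(rng.integers(len(ords)))]
                r = int(rng.integers(2, 7))
                plans.append(_PlannedLoss(species, gid, o, mech, planted_repeat=r))
                chosen = [o]
            for o in chosen:
                avail[gid].discard(o)
                taken.add((gid, o))
                planted += 1
    return plans


# -------------------------------------------------------------- evolution


def evolve_clade(
    cfg: SimulationConfig, ancestor: list[SimGene], rng
) -> tuple[dict[str, list[SimGene]], SimTruth]:
    """Derive the five species' gene sets and the ground-truth event table."""
    plans = plan_losses(cfg, ancestor, rng)
    # NHEJ microhomology is ancestral: plant repeats before copying lineages
    by_id = {g.anc_id: g for g in ancestor}
    for p in plans:
        if p.mechanism == "nhej":
            idx = next(
                i for i, it in enumerate(by_id[p.gene].introns) if it.anc_ordinal == p.anc_ordinal
            )
            while p.planted_repeat >= 2 and not plant_repeat(by_id[p.gene], idx, p.planted_repeat):
                p.planted_repeat -= 1

    species_genes: dict[str, list[SimGene]] = {}
    records: list[TruthRecord] = []
    for sp in SPECIES:
        genes = [g.copy() for g in ancestor]
        gmap = {g.anc_id: g for g in genes}
        rate = cfg.substitution_rates.get(sp, 0.0)
        for g in genes:
            substitute_gene(g, rate, rng)
        for p in [q for q in plans if q.species == sp]:
            g = gmap[p.gene]
            idx = next(
                (i for i, it in enumerate(g.introns) if it.anc_ordinal == p.anc_ordinal), None
            )
            if idx is None:
                continue
            anc_offset = g.intron_offsets()[idx]
            deletion = p.exon_deletion if p.mechanism == "genomic_deletion" else 0
            ok = remove_intron(g, idx, exon_deletion=deletion, rng=rng)
            if not ok and deletion:
                ok = remove_intron(g, idx)  # fall back to a precise removal
                deletion = 0
            if not ok:
                continue
            precise = deletion == 0
            if p.mechanism == "reverse_transcription" and cfg.gc_elevation_at_loss > 0:
                elevate_flank_gc(
                    g, anc_offset - (0 if precise else deletion // 2), cfg.gc_window,
                    cfg.gc_elevation_at_loss, rng,
                )
            records.append(
                TruthRecord(
                    species=sp,
                    gene=p.gene,
                    event="loss",
                    anc_ordinal=p.anc_ordinal,
                    mechanism=p.mechanism,
                    precise=precise,
                    flank_indel_bp=deletion,
                    planted_repeat=p.planted_repeat,
                    anc_offset=anc_offset,
                )
            )
        species_genes[sp] = genes

    # gains: copy a recorded source segment, wrap in GT..AG, insert
    gain_n = 0
    for sp, count in cfg.gain_counts.items():
        genes = species_genes[sp]
        donors = [
            g for g in genes if g.strand == "+" and any(len(i.seq) >= 40 for i in g.introns)
        ]
        for _ in range(count):
            gain_n += 1
            host = None
            for _attempt in range(200):
                cand = genes[int(rng.integers(len(genes)))]
                cds_len = len(cand.spliced_cds)
                off = 6 + int(rng.integers(cds_len - 12))
                if any(abs(off - o) < 12 for o in cand.intron_offsets()):
                    continue
                host = cand
                break
            if host is None:
                raise RuntimeError("could not place gained intron")
            donor = donors[int(rng.integers(len(donors)))]
            donor_intr = next(i for i in donor.introns if len(i.seq) >= 40)
            src_len = int(rng.integers(30, min(len(donor_intr.seq) - 4, 120)))
            segment = donor_intr.seq[2 : 2 + src_len]
            new_seq = "GT" + segment + "AG"
            # split the host exon containing `off`
            acc = 0
            for i, exon in enumerate(host.exons):
                if acc < off < acc + len(exon):
                    cut = off - acc
                    host.exons[i : i + 1] = [exon[:cut], exon[cut:]]
                    host.introns.insert(i, SimIntron(0, new_seq))
                    break
                acc += len(exon)
            # id convention shared with the pipeline: <species gene id>:<cds offset>
            intron_id = f"{sp}_{host.anc_id}:{off}"
            detectable = rng.random() < cfg.gain_source_detectable_frac
            records.append(
                TruthRecord(
                    species=sp,
                    gene=host.anc_id,
                    event="gain",
                    anc_ordinal=0,
                    mechanism="gain",
                    precise=True,
                    flank_indel_bp=0,
                    planted_repeat=0,
                    anc_offset=off,
                    gain_source=f"{donor.anc_id}.intron{donor_intr.anc_ordinal}" if detectable else "",
                    intron_id=intron_id,
                )
            )
    truth = SimTruth(
        run_id=cfg.run_id,
        records=records,
        n_ancestral_introns={g.anc_id: len(g.introns) for g in ancestor},
    )
    return species_genes, truth


# ----------------------------------------------------------------- output


def _layout_species(sp: str, genes: list[SimGene], rng):
    """Concatenate genes (with AT-rich spacers) into one chromosome; return
    the sequence, GFF3 rows, junction records and per-gene genomic spans."""
    chrom = f"{sp}_chr1"
    parts: list[str] = []
    pos = 0
    gff = ["##gff-version 3"]
    junctions = []
    spans: dict[str, dict] = {}

    def spacer() -> str:
        n = int(rng.integers(200, 400))
        return "".join(rng.choice(_BASES, size=n, p=np.array([0.42, 0.42, 0.08, 0.08])))

    for g in genes:
        sp_seq = spacer()
        parts.append(sp_seq)
        pos += len(sp_seq)
        pieces = []
        for i, exon in enumerate(g.exons):
            pieces.append(("exon", exon))
            if i < len(g.introns):
                pieces.append(("intron", g.introns[i].seq))
        gene_seq = "".join(s for _, s in pieces)
        gid = f"{sp}_{g.anc_id}"
        start = pos
        if g.strand == "+":
            cursor = start
            cds_segs, intr_spans = [], []
            for kind, s in pieces:
                if kind == "exon":
                    cds_segs.append((cursor, cursor + len(s)))
                else:
                    intr_spans.append((cursor, cursor + len(s)))
                cursor += len(s)
            parts.append(gene_seq)
        else:
            placed = _revcomp(gene_seq)
            parts.append(placed)
            L = len(gene_seq)
            cursor = 0
            cds_segs, intr_spans = [], []
            for kind, s in pieces:
                t0, t1 = cursor, cursor + len(s)
                g0, g1 = start + L - t1, start + L - t0
                (cds_segs if kind == "exon" else intr_spans).append((g0, g1))
                cursor += len(s)
        pos += len(gene_seq)
        lo = min(s for s, _ in cds_segs) + 1
        hi = max(e for _, e in cds_segs)
        gff.append(f"{chrom}\tsim\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\tID={gid}")
        gff.append(f"{chrom}\tsim\tmRNA\t{lo}\t{hi}\t.\t{g.strand}\t.\tID={gid}.1;Parent={gid}")
        for s, e in sorted(cds_segs):
            gff.append(
                f"{chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\tID=cds-{gid};Parent={gid}.1"
            )
        for j, (s, e) in enumerate(sorted(intr_spans)):
            junctions.append((chrom, s, e, f"{gid}.junc{j}", g.strand))
        spans[g.anc_id] = {
            "gene_id": gid,
            "cds_segs": sorted(cds_segs),
            "intron_spans": sorted(intr_spans),
            "start": start,
            "strand": g.strand,
        }
    parts.append(spacer())
    return chrom, "".join(parts), gff, junctions, spans


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _hit_row(q, s, pident, length, evalue, bitscore, qstart=1, qend=None, sstart=1, send=None):
    qend = qend or length
    send = send or length
    return f"{q}\t{s}\t{pident:.2f}\t{length}\t0\t0\t{qstart}\t{qend}\t{sstart}\t{send}\t{evalue:.2e}\t{bitscore:.1f}"


@dataclass
class SimulatedClade:
    config: SimulationConfig
    truth: SimTruth
    genes: dict  # species -> list[SimGene]
    fasta: dict  # species -> path
    gff: dict
    junctions: dict
    rbh_hits: dict  # (a, b) -> path
    gain_hits: dict  # species -> path (may be empty file)
    outdir: str


def simulate_clade(cfg: SimulationConfig, outdir: str) -> SimulatedClade:
    """Run the full simulation and write pipeline-ready files under ``outdir``.

    Emits per species a genome FASTA, a GFF3 annotation and a junction BED;
    BLAST-tabular RBH tables for every (DDB, other) pair; a gain-source hit
    table per focal species; and the ground-truth TSV. Identical seeds give
    byte-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    os.makedirs(outdir, exist_ok=True)
    ancestor = build_ancestor(cfg, rng)
    species_genes, truth = evolve_clade(cfg, ancestor, rng)

    fasta, gff_paths, junc_paths, spans_all = {}, {}, {}, {}
    for sp in SPECIES:
        chrom, seq, gff, junctions, spans = _layout_species(sp, species_genes[sp], rng)
        spans_all[sp] = spans
        fasta[sp] = os.path.join(outdir, f"{sp}.fasta")
        with open(fasta[sp], "w") as fh:
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
        gff_paths[sp] = os.path.join(outdir, f"{sp}.gff3")
        with open(gff_paths[sp], "w") as fh:
            fh.write("\n".join(gff) + "\n")
        junc_paths[sp] = os.path.join(outdir, f"{sp}.junctions.bed")
        with open(junc_paths[sp], "w") as fh:
            for chrom_, s, e, name, strand in junctions:
                count = int(rng.poisson(15)) + 1
                fh.write(f"{chrom_}\t{s}\t{e}\t{name}\t{count}\t{strand}\n")

    # RBH tables from the simulator's own ortholog knowledge
    rbh = {}
    anchor = "DDB"
    for other in SPECIES:
        if other == anchor:
            continue
        fwd = os.path.join(outdir, f"{anchor}_vs_{other}.tsv")
        rev = os.path.join(outdir, f"{other}_vs_{anchor}.tsv")
        with open(fwd, "w") as f1, open(rev, "w") as f2:
            for g in ancestor:
                qa = f"{anchor}_{g.anc_id}"
                qb = f"{other}_{g.anc_id}"
                L = len(g.spliced_cds) // 3
                f1.write(_hit_row(qa, qb, 85.0, L, 1e-180, 2.0 * L) + "\n")
                f2.write(_hit_row(qb, qa, 85.0, L, 1e-180, 2.0 * L) + "\n")
        rbh[(anchor, other)] = fwd
        rbh[(other, anchor)] = rev

    # gain-source hit tables (query = gained intron sequence id)
    gain_hits = {}
    for sp in cfg.gain_counts:
        path = os.path.join(outdir, f"{sp}.gain_hits.tsv")
        rows = []
        for rec in truth.gains(sp):
            spans = spans_all[sp][rec.gene]
            host_gid = spans["gene_id"]
            # locate the gained intron by its spliced-CDS offset
            gene = next(g for g in species_genes[sp] if g.anc_id == rec.gene)
            offsets = gene.intron_offsets()
            idx = next(
                i for i, it in enumerate(gene.introns)
                if it.anc_ordinal == 0 and offsets[i] == rec.anc_offset
            )
            gspan = spans["intron_spans"][idx if gene.strand == "+" else len(gene.introns) - 1 - idx]
            ilen = len(gene.introns[idx].seq)
            chrom = f"{sp}_chr1"
            qid = rec.intron_id
            # self-hit: the intron's own locus
            rows.append(
                _hit_row(qid, chrom, 100.0, ilen, 1e-60, 2 * ilen, 1, ilen, gspan[0] + 1, gspan[1])
            )
            if rec.gain_source:
                donor_anc, intron_tag = rec.gain_source.split(".intron")
                dspans = spans_all[sp][donor_anc]
                donor_gene = next(g for g in species_genes[sp] if g.anc_id == donor_anc)
                didx = next(
                    i for i, it in enumerate(donor_gene.introns)
                    if it.anc_ordinal == int(intron_tag)
                )
                dspan = dspans["intron_spans"][didx]
                rows.append(
                    _hit_row(
                        qid, chrom, 98.0, ilen, 1e-40, 1.8 * ilen,
                        1, ilen, dspan[0] + 3, dspan[0] + 2 + ilen,
                    )
                )
            # a decoy that must be rejected on e-value
            rows.append(_hit_row(qid, chrom, 90.0, ilen, 1e-4, 30.0, 1, ilen, 1, ilen))
        with open(path, "w") as fh:
            fh.write("\n".join(rows) + ("\n" if rows else ""))
        gain_hits[sp] = path

    _write_truth(truth, os.path.join(outdir, "truth.tsv"))
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump({"run_id": cfg.run_id, "seed": cfg.seed, "n_genes": cfg.n_genes}, fh, indent=1)
    return SimulatedClade(
        config=cfg,
        truth=truth,
        genes=species_genes,
        fasta=fasta,
        gff=gff_paths,
        junctions=junc_paths,
        rbh_hits=rbh,
        gain_hits=gain_hits,
        outdir=outdir,
    )


def _write_truth(truth: SimTruth, path: str) -> None:
    cols = [
        "run_id", "species", "gene", "event", "anc_ordinal", "mechanism",
        "precise", "flank_indel_bp", "planted_repeat", "anc_offset",
        "gain_source", "intron_id",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in truth.records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        truth.run_id, r.species, r.gene, r.event, r.anc_ordinal,
                        r.mechanism, int(r.precise), r.flank_indel_bp,
                        r.planted_repeat, r.anc_offset, r.gain_source, r.intron_id,
                    )
                )
                + "\n"
            )


def read_truth(path: str) -> SimTruth:
    records = []
    run_id = ""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            f = dict(zip(header, line.rstrip("\n").split("\t")))
            run_id = f["run_id"]
            records.append(
                TruthRecord(
                    species=f["species"], gene=f["gene"], event=f["event"],
                    anc_ordinal=int(f["anc_ordinal"]), mechanism=f["mechanism"],
                    precise=bool(int(f["precise"])), flank_indel_bp=int(f["flank_indel_bp"]),
                    planted_repeat=int(f["planted_repeat"]), anc_offset=int(f["anc_offset"]),
                    gain_source=f["gain_source"], intron_id=f["intron_id"],
                )
            )
    return SimTruth(run_id=run_id, records=records)


# --------------------------------------------------------------- recovery


@dataclass
class RecoveryReport:
    run_id: str
    loss_sensitivity: float
    loss_precision: float
    by_mechanism: dict
    precision_accuracy: float | None
    gain_sensitivity: float
    gain_precision: float
    n_true_losses: int
    n_called_losses: int
    n_true_gains: int
    n_called_gains: int

    def to_dict(self) -> dict:
        return asdict(self)


def truth_compare(pipeline_summary: dict, truth: SimTruth) -> RecoveryReport:
    """Score pipeline loss/gain calls against the simulation's ground truth.

    Losses are matched on (species, ancestral gene, ancestral ordinal); the
    pipeline's site ordinals are ancestral ranks as long as every ancestral
    intron survives in at least one lineage. Raises if the summary and truth
    come from different runs.
    """
    if pipeline_summary.get("run_id") and pipeline_summary["run_id"] != truth.run_id:
        raise ValueError(
            f"run id mismatch: calls {pipeline_summary['run_id']!r} vs truth {truth.run_id!r}"
        )
    def norm(gene: str) -> str:
        head, _, tail = gene.partition("_")
        return tail if head in SPECIES and tail else gene

    called = {
        (c["species"], norm(c["gene"]), c["ordinal"]): c
        for c in pipeline_summary.get("loss_records", [])
    }
    true_losses = {(r.species, r.gene, r.anc_ordinal): r for r in truth.losses()}
    tp_keys = called.keys() & true_losses.keys()
    sens = len(tp_keys) / len(true_losses) if true_losses else 1.0
    prec = len(tp_keys) / len(called) if called else 1.0
    by_mech: dict[str, dict] = {}
    for mech in {r.mechanism for r in truth.losses()}:
        keys = {k for k, r in true_losses.items() if r.mechanism == mech}
        by_mech[mech] = {
            "n_true": len(keys),
            "sensitivity": len(keys & called.keys()) / len(keys) if keys else 1.0,
        }
    matched = [(called[k], true_losses[k]) for k in tp_keys]
    if matched:
        acc = sum(1 for c, r in matched if bool(c["precise"]) == r.precise) / len(matched)
    else:
        acc = None
    called_gains = {
        (c["species"], norm(c["gene"])) for c in pipeline_summary.get("gain_records", [])
    }
    true_gains = {(r.species, r.gene) for r in truth.gains()}
    g_tp = called_gains & true_gains
    return RecoveryReport(
        run_id=truth.run_id,
        loss_sensitivity=sens,
        loss_precision=prec,
        by_mechanism=by_mech,
        precision_accuracy=acc,
        gain_sensitivity=len(g_tp) / len(true_gains) if true_gains else 1.0,
        gain_precision=len(g_tp) / len(called_gains) if called_gains else 1.0,
        n_true_losses=len(true_losses),
        n_called_losses=len(called),
        n_true_gains=len(true_gains),
        n_called_gains=len(called_gains),
    )
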