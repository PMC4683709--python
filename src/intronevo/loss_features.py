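"""Per-loss characterisation: precision, adjacency, repeats, position and GC.

These are the site-level quantities used to discriminate the three loss
mechanisms: reverse transcription predicts precise, 3'-biased, adjacent
co-losses with gene-conversion (GC-elevated) flanks; genomic deletion
predicts flanking exonic indels; NHEJ repair predicts short direct repeats
at the lost intron's boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome_io import GeneModel, Intron
from .orthology import GAP, CodingAlignment, offset_to_column
from . import stats as _stats

logger = logging.getLogger(__name__)

#: codon prefixes whose third position is 4-fold degenerate (standard code)
FOURFOLD_PREFIXES = frozenset(["CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"])


@dataclass
class LossFeature:
    """All mechanism-relevant features of one called intron loss."""

    loss_id: str
    gene_id: str
    species: str
    ordinal: int
    precise: bool
    flank_indel_bp: int
    relative_position: float
    intron_length: int
    repeat_len_5p: int
    repeat_len_3p: int
    flank_gc: float | None
    relative_gc: float | None
    fourfold_gc: float | None


@dataclass
class GCContext:
    """Exonic flank windows around an intron position and their pooled GC."""

    window_bp: int
    left_seq: str
    right_seq: str
    pooled_gc: float | None
    gc_left: float | None = None
    gc_right: float | None = None


def classify_precision(
    aln_column: int, alignment: CodingAlignment, window: int = 15
) -> tuple[bool, int]:
    """Precise iff no gap columns fall within ``window`` aligned-CDS columns
    of the lost-intron position on either side.

    Imprecise losses report the summed gap length in that window — the
    flanking exonic indel footprint.
    """
    a, b = alignment.aligned_cds_a, alignment.aligned_cds_b
    lo = max(aln_column - window, 0)
    hi = min(aln_column + window, len(a))
    indel = sum(1 for i in range(lo, hi) if a[i] == GAP or b[i] == GAP)
    return indel == 0, indel


def adjacent_loss_pairs(lost_ordinals_by_gene: dict[str, list[int]]) -> int:
    """Count consecutive-ordinal loss pairs, summed over genes.

    Ordinals refer to the ancestral (pre-loss) gene structure; a run of three
    adjacent lost introns counts as two pairs.
    """
    total = 0
    for ordinals in lost_ordinals_by_gene.values():
        s = set(ordinals)
        total += sum(1 for o in s if o + 1 in s)
    return total


def direct_repeat_length(
    upstream_exon: str, intron_seq: str, downstream_exon: str, k_max: int = 10
) -> tuple[int, int]:
    """Longest direct repeats shared by the intron boundary and adjacent exon.

    ``repeat_len_5p`` matches the intron's 5' end against the downstream
    exon's start; ``repeat_len_3p`` matches the upstream exon's end against
    the intron's 3' end. Either repeat permits a deletion that removes the
    intron precisely. Searches are capped at the available sequence length.
    """

    def prefix_match(x: str, y: str) -> int:
        k = 0
        for a, b in zip(x[:k_max], y[:k_max]):
            if a != b or a == "N":
                break
            k += 1
        return k

    rep5 = prefix_match(intron_seq, downstream_exon)
    rep3 = prefix_match(upstream_exon[::-1], intron_seq[::-1])
    return rep5, rep3


def repeat_frequency_compare(
    lost_repeats: list[int], conserved_repeats: list[int], k: int
) -> tuple[tuple[int, int, int, int], float, float]:
    """2x2 comparison of repeat incidence (max repeat >= k) in lost vs
    conserved sites; returns the table, chi-square and p."""
    a = sum(1 for r in lost_repeats if r >= k)
    b = len(lost_repeats) - a
    c = sum(1 for r in conserved_repeats if r >= k)
    d = len(conserved_repeats) - c
    chi2, p = _stats.chi_square_2x2(a, b, c, d)
    return (a, b, c, d), chi2, p


def relative_intron_position(intron: Intron, gene: GeneModel) -> float:
    """Fraction of the spliced CDS upstream of the intron (0 = 5' end)."""
    return intron.cds_offset / len(gene.spliced_cds)


def _gc(seq: str) -> tuple[int, int]:
    gc = sum(1 for c in seq if c in "GC")
    valid = sum(1 for c in seq if c != "N")
    return gc, valid


def flank_gc(gene: GeneModel, intron: Intron, window: int = 100) -> GCContext:
    """GC content of exonic (spliced-CDS) windows on each side of an intron.

    Windows are truncated at the CDS ends and never reach into neighbouring
    introns; pooled GC uses all non-N bases of both sides. N bases count as
    non-GC and are excluded from the denominator.
    """
    cds = gene.spliced_cds
    off = intron.cds_offset
    left = cds[max(off - window, 0) : off]
    right = cds[off : off + window]
    gl, nl = _gc(left)
    gr, nr = _gc(right)
    pooled = (gl + gr) / (nl + nr) if nl + nr else None
    return GCContext(
        window_bp=window,
        left_seq=left,
        right_seq=right,
        pooled_gc=pooled,
        gc_left=gl / nl if nl else None,
        gc_right=gr / nr if nr else None,
    )


def relative_flank_gc(
    site_gc: float, conserved_gcs_same_gene: list[float]
) -> float | None:
    """Site flank GC divided by the median flank GC of the same gene's
    conserved introns; ``None`` when no conserved intron (or zero median)."""
    vals = [g for g in conserved_gcs_same_gene if g is not None]
    if not vals:
        return None
    med = float(np.median(vals))
    if med == 0:
        logger.warning("zero median conserved-flank GC; relative GC undefined")
        return None
    return site_gc / med


def fourfold_gc(gene: GeneModel, intron: Intron, window: int = 100) -> float | None:
    """GC at 4-fold degenerate third positions within the flank windows.

    Windows are trimmed to whole codons of the CDS reading frame; returns
    ``None`` when no 4-fold codon falls inside them.
    """
    cds = gene.spliced_cds
    off = intron.cds_offset
    spans = []
    lo = max(off - window, 0)
    lo += (3 - lo % 3) % 3  # round start up to a codon boundary
    hi = off - off % 3  # round end down
    if hi > lo:
        spans.append((lo, hi))
    lo2 = off + (3 - off % 3) % 3
    hi2 = min(off + window, len(cds))
    hi2 -= hi2 % 3
    if hi2 > lo2:
        spans.append((lo2, hi2))
    thirds = []
    for lo, hi in spans:
        for i in range(lo, hi, 3):
            codon = cds[i : i + 3]
            if codon[:2] in FOURFOLD_PREFIXES and codon[2] != "N":
                thirds.append(codon[2])
    if not thirds:
        return None
    return sum(1 for c in thirds if c in "GC") / len(thirds)
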