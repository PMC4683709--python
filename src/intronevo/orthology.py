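"""Ortholog detection, codon alignment and intron-position projection.

One-to-one orthologs are called by reciprocal best hits (RBH) on BLAST
tabular output. Proteins are aligned globally (BLOSUM62, affine gaps), the
alignment is expanded to codons, and each intron is projected to the aligned
CDS column given by its spliced-CDS offset. Two introns mark the *same* site
only when they land on the same aligned column with the same phase — a 1-nt
slide changes the phase and yields two discordant sites.

Sites in poorly aligned neighbourhoods (flank similarity below a threshold,
the dataset's first quartile in the original analysis) are discarded, and
extant introns at discordant positions can additionally be required to carry
exact splice-junction support from RNA-seq.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import Intron

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class HitRecord:
    """One row of BLAST tabular (outfmt 6) output."""

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    evalue: float
    bitscore: float
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0

    def __post_init__(self) -> None:
        if self.evalue < 0 or not 0 <= self.percent_identity <= 100:
            raise ValueError(f"invalid hit record {self.query_id}->{self.subject_id}")


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str


@dataclass
class CodingAlignment:
    """Protein-guided codon alignment of an ortholog pair.

    The CDS tier is the protein alignment expanded 3x, with '---' per protein
    gap; removing gaps from either tier recovers the input sequences.
    """

    pair: OrthologPair
    aligned_protein_a: str
    aligned_protein_b: str
    aligned_cds_a: str
    aligned_cds_b: str


@dataclass
class IntronSiteCall:
    """One intron position projected across an ortholog pair."""

    pair: OrthologPair
    aln_column: int  # 0-based column in the aligned CDS
    phase: int
    status: str  # conserved | discordant_a_only | discordant_b_only |
    #              discarded_low_quality | discarded_junction
    intron_a: Intron | None = None
    intron_b: Intron | None = None
    sim_left: float | None = None
    sim_right: float | None = None
    meta: dict = field(default_factory=dict)


def read_blast_tab(path: str) -> list[HitRecord]:
    """Parse BLAST outfmt 6 (12 standard columns) into hit records."""
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            hits.append(
                HitRecord(
                    query_id=f[0],
                    subject_id=f[1],
                    percent_identity=float(f[2]),
                    aln_length=int(f[3]),
                    qstart=int(f[6]),
                    qend=int(f[7]),
                    sstart=int(f[8]),
                    send=int(f[9]),
                    evalue=float(f[10]),
                    bitscore=float(f[11]),
                )
            )
    return hits


def _best_hits(hits: list[HitRecord], evalue_max: float, identity_min: float) -> dict[str, str]:
    """Best subject per query after threshold filtering.

    Ties on bitscore break to lowest e-value, then highest identity, then
    lexicographic subject id (with an ambiguity warning).
    """
    best: dict[str, HitRecord] = {}
    for h in hits:
        if h.evalue > evalue_max or h.percent_identity < identity_min:
            continue
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key_new = (-h.bitscore, h.evalue, -h.percent_identity, h.subject_id)
        key_cur = (-cur.bitscore, cur.evalue, -cur.percent_identity, cur.subject_id)
        if key_new < key_cur:
            best[h.query_id] = h
        if (
            h.subject_id != cur.subject_id
            and key_new[:3] == key_cur[:3]
        ):
            logger.warning("ambiguous best hit for %s (tie on score)", h.query_id)
    return {q: h.subject_id for q, h in best.items()}


def reciprocal_best_hits(
    hits_ab: list[HitRecord],
    hits_ba: list[HitRecord],
    evalue_max: float = 1e-10,
    identity_min: float = 25.0,
) -> list[OrthologPair]:
    """One-to-one orthologs as reciprocal best hits.

    Hits failing the e-value or percent-identity thresholds are dropped before
    best-hit selection; a pair is retained iff each gene is the other's best
    surviving hit. An empty filtered hit set yields an empty result.
    """
    best_ab = _best_hits(hits_ab, evalue_max, identity_min)
    best_ba = _best_hits(hits_ba, evalue_max, identity_min)
    pairs = [
        OrthologPair(a, b)
        for a, b in sorted(best_ab.items())
        if best_ba.get(b) == a
    ]
    return pairs


_aligner = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -10.0
        a.extend_gap_score = -0.5
        a.mode = "global"
        _aligner = a
    return _aligner


def align_proteins(protein_a: str, protein_b: str) -> tuple[str, str, float]:
    """Global protein alignment (BLOSUM62, gap open 10, extend 0.5).

    Returns ``(aligned_a, aligned_b, score)``; the traceback is deterministic
    (first optimal path in the aligner's canonical order).
    """
    if not protein_a or not protein_b:
        raise ValueError("cannot align empty protein sequence")
    aln = _get_aligner().align(protein_a, protein_b)[0]
    sa, sb = aln[0], aln[1]
    return str(sa), str(sb), float(aln.score)


def codon_expand(pair: OrthologPair, aligned_a: str, aligned_b: str,
                 cds_a: str, cds_b: str) -> CodingAlignment:
    """Expand a protein alignment to a codon alignment.

    ``cds_a``/``cds_b`` are the spliced coding sequences (a trailing stop
    codon is tolerated and trimmed).
    """

    def expand(aligned: str, cds: str) -> str:
        n_aa = len(aligned) - aligned.count(GAP)
        if len(cds) == 3 * n_aa + 3:
            cds = cds[:-3]  # trailing stop codon
        if len(cds) != 3 * n_aa:
            raise ValueError(f"CDS length {len(cds)} does not match {n_aa} aligned residues")
        out, i = [], 0
        for ch in aligned:
            if ch == GAP:
                out.append("---")
            else:
                out.append(cds[i : i + 3])
                i += 3
        return "".join(out)

    return CodingAlignment(pair, aligned_a, aligned_b, expand(aligned_a, cds_a), expand(aligned_b, cds_b))


def offset_to_column(aligned_cds: str, cds_offset: int) -> int:
    """Aligned-CDS column reached after consuming ``cds_offset`` real bases.

    The smallest such column is returned, so a boundary that abuts a gap run
    maps to the column before the gaps.
    """
    count = 0
    for col, ch in enumerate(aligned_cds):
        if count == cds_offset:
            return col
        if ch != GAP:
            count += 1
    if count == cds_offset:
        return len(aligned_cds)
    raise ValueError(f"cds_offset {cds_offset} beyond ungapped length {count}")


def column_to_offset(aligned_cds: str, column: int) -> int:
    """Number of ungapped bases of ``aligned_cds`` before ``column``."""
    return sum(1 for ch in aligned_cds[:column] if ch != GAP)


def project_intron_sites(
    alignment: CodingAlignment,
    introns_a: list[Intron],
    introns_b: list[Intron],
) -> list[IntronSiteCall]:
    """Project the introns of both orthologs onto aligned-CDS columns.

    Introns meeting at the same column with the same phase form one conserved
    site; all others yield discordant sites. Every input intron appears in
    exactly one returned call.
    """
    ungapped_a = len(alignment.aligned_cds_a) - alignment.aligned_cds_a.count(GAP)
    ungapped_b = len(alignment.aligned_cds_b) - alignment.aligned_cds_b.count(GAP)
    sites: dict[tuple[int, int], dict] = {}
    for intr, which, limit, cds in (
        *((i, "a", ungapped_a, alignment.aligned_cds_a) for i in introns_a),
        *((i, "b", ungapped_b, alignment.aligned_cds_b) for i in introns_b),
    ):
        if not 0 < intr.cds_offset < limit + 3:  # tolerate trimmed stop codon
            raise ValueError(
                f"intron offset {intr.cds_offset} invalid for gene {intr.gene_id}"
            )
        col = offset_to_column(cds, min(intr.cds_offset, limit))
        key = (col, intr.phase)
        sites.setdefault(key, {})[which] = intr
    calls = []
    for (col, phase), found in sorted(sites.items()):
        if "a" in found and "b" in found:
            status = "conserved"
        elif "a" in found:
            status = "discordant_a_only"
        else:
            status = "discordant_b_only"
        calls.append(
            IntronSiteCall(
                pair=alignment.pair,
                aln_column=col,
                phase=phase,
                status=status,
                intron_a=found.get("a"),
                intron_b=found.get("b"),
            )
        )
    return calls


def flank_similarity(
    alignment: CodingAlignment, aln_column: int, window: int = 45
) -> tuple[float, float]:
    """Per-side similarity in ``window`` aligned-CDS columns around a site.

    Similarity is the fraction of columns where both sequences carry the same
    non-gap base; gap columns count as mismatches. Windows truncated by the
    alignment end use the available column count as denominator.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    a, b = alignment.aligned_cds_a, alignment.aligned_cds_b

    def side(lo: int, hi: int) -> float:
        lo, hi = max(lo, 0), min(hi, len(a))
        if hi <= lo:
            return 0.0
        same = sum(
            1 for i in range(lo, hi) if a[i] == b[i] and a[i] != GAP and a[i] != "N"
        )
        return same / (hi - lo)

    return side(aln_column - window, aln_column), side(aln_column, aln_column + window)


def annotate_similarities(
    alignment: CodingAlignment, sites: list[IntronSiteCall], window: int = 45
) -> None:
    for s in sites:
        s.sim_left, s.sim_right = flank_similarity(alignment, s.aln_column, window)


def whole_alignment_similarity(alignment: CodingAlignment) -> float:
    a, b = alignment.aligned_cds_a, alignment.aligned_cds_b
    if not a:
        return 0.0
    same = sum(1 for x, y in zip(a, b) if x == y and x != GAP)
    return same / len(a)


def filter_sites(
    sites: list[IntronSiteCall],
    min_similarity: float = 0.5,
    alignment_similarities: list[float] | None = None,
) -> tuple[list[IntronSiteCall], float | None]:
    """Discard sites whose flank similarity falls below the threshold.

    A site is marked ``discarded_low_quality`` when either side is below
    ``min_similarity``. If whole-alignment similarities are supplied, their
    first quartile (linear interpolation, numpy default) is returned so the
    threshold can be re-derived for a dataset; otherwise ``None``.
    """
    for s in sites:
        if s.sim_left is None or s.sim_right is None:
            raise ValueError("similarities must be annotated before filtering")
        if s.status.startswith("discarded"):
            continue
        if s.sim_left < min_similarity or s.sim_right < min_similarity:
            s.status = "discarded_low_quality"
    q1 = None
    if alignment_similarities:
        q1 = float(np.percentile(np.asarray(alignment_similarities, dtype=float), 25))
        logger.info("first quartile of whole-alignment similarities: %.4f", q1)
    return sites, q1


def read_junction_bed(path: str) -> dict[tuple[str, int, int], int]:
    """Read splice junctions from 6-column or BED12 junction files.

    Returns ``{(chrom, start, end): read_count}`` with 0-based half-open
    intron coordinates. For BED12 (e.g. TopHat junctions.bed) the intron is
    derived from the two block boundaries.
    """
    junctions: dict[tuple[str, int, int], int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            try:
                if len(f) >= 12:
                    chrom, start = f[0], int(f[1])
                    count = int(float(f[4]))
                    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                    starts = [int(x) for x in f[11].rstrip(",").split(",")]
                    if len(sizes) != 2:
                        raise ValueError("expected 2 blocks")
                    jstart = start + starts[0] + sizes[0]
                    jend = start + starts[1]
                elif len(f) >= 5:
                    chrom, jstart, jend = f[0], int(f[1]), int(f[2])
                    count = int(float(f[4]))
                else:
                    raise ValueError("too few columns")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"malformed BED line {lineno} in {path}: {exc}") from None
            key = (chrom, jstart, jend)
            junctions[key] = junctions.get(key, 0) + count
    return junctions


def junction_filter(
    sites: list[IntronSiteCall],
    junctions: dict[tuple[str, int, int], int] | None,
    min_reads: int = 1,
    species_of: str = "both",
) -> list[IntronSiteCall]:
    """Require exact splice-junction support for extant introns at discordant sites.

    An intron is confirmed iff a junction matching both splice sites exactly
    carries at least ``min_reads`` reads. Unconfirmed introns mark the site
    ``discarded_junction``. With no junction data the sites are returned
    unchanged (absence of evidence is not treated as evidence against).
    """
    if junctions is None:
        logger.warning("no junction data supplied; discordant sites retained unchanged")
        return sites

    def confirmed(intr: Intron) -> bool:
        return junctions.get((intr.chrom_id, intr.genomic_start, intr.genomic_end), 0) >= min_reads

    for s in sites:
        if s.status == "discordant_a_only" and s.intron_a is not None:
            if not confirmed(s.intron_a):
                s.status = "discarded_junction"
        elif s.status == "discordant_b_only" and s.intron_b is not None:
            if not confirmed(s.intron_b):
                s.status = "discarded_junction"
    return sites
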