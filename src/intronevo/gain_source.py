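"""Source-sequence evidence for putative intron gains.

A gained intron is only a strong case when a source element can be named.
Candidate hits of the intron sequence against the genomes are filtered on
E-value, query coverage and similarity, after removing hits to the intron's
own locus. A side statistic compares reverse-transcriptase gene copy numbers
between species, a proxy for reverse-transcription activity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .orthology import HitRecord

#: thresholds for retaining a source-sequence hit
EVALUE_MAX, COVERAGE_MIN, SIMILARITY_MIN = 1e-10, 0.80, 0.85


@dataclass
class SourceCandidate:
    intron_id: str
    hit: HitRecord
    coverage: float
    similarity: float
    verdict: str  # retained | rejected_evalue | rejected_coverage |
    #               rejected_similarity | rejected_self


@dataclass
class CopyNumberSummary:
    """Distinct protein models hit per species, and their ratio."""

    counts: dict[str, int]
    ratio: float | None


def filter_source_hits(
    hits: list[HitRecord],
    intron_lengths: dict[str, int],
    intron_loci: dict[str, tuple[str, int, int]] | None = None,
    evalue_max: float = EVALUE_MAX,
    cov_min: float = COVERAGE_MIN,
    sim_min: float = SIMILARITY_MIN,
) -> list[SourceCandidate]:
    """Assign a verdict to every candidate source hit.

    Queries are gained-intron sequences. Hits overlapping the intron's own
    genomic locus (same chromosome, >= 1 bp overlap) are ``rejected_self``;
    the rest must pass all three thresholds, checked in the order e-value,
    coverage (aligned length / intron length, capped at 1), similarity
    (fraction identity). Thresholds are conjunctive, so the check order does
    not change which hits are retained.
    """
    out = []
    for h in hits:
        if h.query_id not in intron_lengths:
            raise KeyError(f"unknown intron id in hits: {h.query_id}")
        coverage = min(h.aln_length / intron_lengths[h.query_id], 1.0)
        similarity = h.percent_identity / 100.0
        verdict = "retained"
        locus = (intron_loci or {}).get(h.query_id)
        if locus is not None and h.subject_id == locus[0]:
            s, e = sorted((h.sstart, h.send))
            if s - 1 < locus[2] and e > locus[1]:  # 1-based inclusive vs half-open
                verdict = "rejected_self"
        if verdict == "retained" and h.evalue > evalue_max:
            verdict = "rejected_evalue"
        if verdict == "retained" and coverage < cov_min:
            verdict = "rejected_coverage"
        if verdict == "retained" and similarity < sim_min:
            verdict = "rejected_similarity"
        out.append(SourceCandidate(h.query_id, h, coverage, similarity, verdict))
    return out


def splice_boundary_check(intron_seq: str) -> bool:
    """Canonical spliceosomal boundaries: starts GT, ends AG."""
    if not intron_seq:
        raise ValueError("empty intron sequence")
    return intron_seq.startswith("GT") and intron_seq.endswith("AG")


def rt_copy_numbers(
    query_hits_by_species: dict[str, list[HitRecord]],
    evalue_max: float = EVALUE_MAX,
    ratio_between: tuple[str, str] | None = None,
) -> CopyNumberSummary:
    """Reverse-transcriptase copy numbers per species from BLASTP hit tables.

    The copy number is the count of distinct subject protein models with at
    least one hit passing the e-value threshold. The ratio is taken between
    ``ratio_between`` (default: the first two species in input order); a zero
    denominator leaves it undefined.
    """
    counts = {
        sp: len({h.subject_id for h in hits if h.evalue <= evalue_max})
        for sp, hits in query_hits_by_species.items()
    }
    species = ratio_between or tuple(counts)[:2]
    ratio = None
    if len(species) == 2 and counts.get(species[1]):
        ratio = counts[species[0]] / counts[species[1]]
    return CopyNumberSummary(counts=counts, ratio=ratio)
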