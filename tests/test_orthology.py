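"""RBH, alignment, intron-site projection and quality filters."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from intronevo.genome_io import Intron
from intronevo.orthology import (
    CodingAlignment,
    HitRecord,
    OrthologPair,
    align_proteins,
    codon_expand,
    filter_sites,
    flank_similarity,
    junction_filter,
    offset_to_column,
    project_intron_sites,
    reciprocal_best_hits,
)

BL62 = substitution_matrices.load("BLOSUM62")


def hit(q, s, evalue=1e-50, ident=90.0, bits=100.0):
    return HitRecord(q, s, ident, 100, evalue, bits)


class TestRBH:
    def test_mutual_best_pair(self):
        pairs = reciprocal_best_hits([hit("a1", "b1")], [hit("b1", "a1")])
        assert pairs == [OrthologPair("a1", "b1")]

    def test_evalue_threshold_filters_before_selection(self):
        # the only a1 hit fails the e-value cutoff, so no pair survives
        pairs = reciprocal_best_hits([hit("a1", "b1", evalue=1e-9)], [hit("b1", "a1")])
        assert pairs == []

    def test_reciprocity_required(self):
        pairs = reciprocal_best_hits(
            [hit("a1", "b1", bits=100)],
            [hit("b1", "a2", bits=200), hit("b1", "a1", bits=100)],
        )
        assert pairs == []

    def test_identity_threshold(self):
        pairs = reciprocal_best_hits([hit("a1", "b1", ident=20.0)], [hit("b1", "a1")])
        assert pairs == []

    def test_symmetry_under_species_swap(self):
        ab = [hit("a1", "b1"), hit("a2", "b2", bits=80), hit("a2", "b1", bits=60)]
        ba = [hit("b1", "a1"), hit("b2", "a2", bits=80)]
        fwd = {(p.gene_a, p.gene_b) for p in reciprocal_best_hits(ab, ba)}
        rev = {(p.gene_b, p.gene_a) for p in reciprocal_best_hits(ba, ab)}
        assert fwd == rev


def affine_score_oracle(a, b, open_=10.0, ext=0.5):
    """Scalar Gotoh DP: optimal global affine-gap score under BLOSUM62."""
    NEG = -1e9
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (deletion in a... insertion)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -open_ - (i - 1) * ext
    for j in range(1, m + 1):
        Y[0, j] = -open_ - (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BL62[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - open_, X[i - 1, j] - ext, Y[i - 1, j] - open_)
            Y[i, j] = max(M[i, j - 1] - open_, Y[i, j - 1] - ext, X[i, j - 1] - open_)
    return max(M[n, m], X[n, m], Y[n, m])


class TestAlignProteins:
    def test_identical_sequences_gapless(self):
        a, b, _ = align_proteins("MKVLA", "MKVLA")
        assert a == b == "MKVLA"

    def test_single_gap_column(self):
        a, b, _ = align_proteins("MKV", "MV")
        assert len(a) == len(b) == 3
        assert b.count("-") == 1 and a == "MKV"

    @pytest.mark.parametrize("seed", range(6))
    def test_score_matches_scalar_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(aas, size=rng.integers(3, 11)))
        b = "".join(rng.choice(aas, size=rng.integers(3, 11)))
        _, _, score = align_proteins(a, b)
        assert score == pytest.approx(affine_score_oracle(a, b))


def make_alignment(aligned_a, aligned_b, cds_a=None, cds_b=None):
    """Codon alignment straight from aligned protein strings (toy CDS)."""
    codon = {"M": "ATG", "K": "AAA", "V": "GTT", "L": "TTA", "A": "GCT", "G": "GGT"}

    def cds_of(aligned):
        return "".join(codon[c] for c in aligned if c != "-")

    pair = OrthologPair("A", "B")
    return codon_expand(pair, aligned_a, aligned_b, cds_a or cds_of(aligned_a), cds_b or cds_of(aligned_b))


def intron(gene, offset, length=60, seq=None, **kw):
    return Intron(
        gene_id=gene,
        ordinal=1,
        cds_offset=offset,
        phase=offset % 3,
        length=length,
        sequence=seq or ("GT" + "A" * (length - 4) + "AG"),
        **kw,
    )


class TestProjection:
    def test_identical_genes_conserved_site(self):
        aln = make_alignment("MKVLA", "MKVLA")
        calls = project_intron_sites(aln, [intron("A", 10)], [intron("B", 10)])
        assert [c.status for c in calls] == ["conserved"]
        assert calls[0].aln_column == 10 and calls[0].phase == 1

    def test_one_sided_intron_is_discordant(self):
        aln = make_alignment("MKVLA", "MKVLA")
        calls = project_intron_sites(aln, [intron("A", 6)], [])
        assert [c.status for c in calls] == ["discordant_a_only"]

    def test_phase_shift_gives_two_discordant_sites(self):
        # offsets 10 and 11 are one base apart: same neighbourhood, phases 1 vs 2
        aln = make_alignment("MKVLA", "MKVLA")
        calls = project_intron_sites(aln, [intron("A", 10)], [intron("B", 11)])
        assert sorted(c.status for c in calls) == [
            "discordant_a_only",
            "discordant_b_only",
        ]

    def test_gap_aware_column_mapping(self):
        # B lacks the K residue; an intron after A's codon 2 must map past it
        aln = make_alignment("MKVLA", "M-VLA")
        col = offset_to_column(aln.aligned_cds_a, 6)
        assert col == 6
        assert offset_to_column(aln.aligned_cds_b, 3) == 3
        calls = project_intron_sites(aln, [intron("A", 6)], [intron("B", 3)])
        # A's offset-6 column is 6; B's offset-3 maps to column 3 (before gap)
        assert all(c.status != "conserved" for c in calls)

    def test_every_intron_in_exactly_one_call(self):
        aln = make_alignment("MKVLAG", "MKVLAG")
        ia = [intron("A", 3), intron("A", 9)]
        ib = [intron("B", 3), intron("B", 12)]
        calls = project_intron_sites(aln, ia, ib)
        got_a = [c.intron_a for c in calls if c.intron_a]
        got_b = [c.intron_b for c in calls if c.intron_b]
        assert sorted(i.cds_offset for i in got_a) == [3, 9]
        assert sorted(i.cds_offset for i in got_b) == [3, 12]

    def test_self_projection_all_conserved(self):
        aln = make_alignment("MKVLAGKV", "MKVLAGKV")
        ins = [intron("A", 3), intron("A", 12), intron("A", 20)]
        calls = project_intron_sites(aln, ins, ins)
        assert all(c.status == "conserved" for c in calls)


class TestFlankSimilarity:
    def test_identical_flanks(self):
        aln = make_alignment("MKVLAGMKVLAGMKVLAG", "MKVLAGMKVLAGMKVLAG")
        left, right = flank_similarity(aln, 27, window=20)
        assert left == 1.0 and right == 1.0

    def test_mismatched_left_flank_zero(self):
        # codons ATG vs GGT share no base position-wise
        aln = make_alignment("MMMMVV", "GGGGVV")
        left, right = flank_similarity(aln, 12, window=12)
        assert left == 0.0 and right == 1.0

    def test_fraction_counts(self):
        # 45-column flank with 27 identities -> 0.6
        a = "A" * 27 + "C" * 18 + "G" * 45
        b = "A" * 27 + "G" * 18 + "G" * 45
        aln = CodingAlignment(OrthologPair("A", "B"), "", "", a, b)
        left, right = flank_similarity(aln, 45, window=45)
        assert left == pytest.approx(27 / 45) == pytest.approx(0.6)
        assert right == 1.0

    def test_truncated_window_uses_available_columns(self):
        aln = make_alignment("MKV", "MKV")
        left, _ = flank_similarity(aln, 3, window=45)
        assert left == 1.0  # 3 identical columns / 3 available


class TestFilters:
    def _site(self, sl, sr):
        from intronevo.orthology import IntronSiteCall

        s = IntronSiteCall(OrthologPair("A", "B"), 10, 1, "conserved")
        s.sim_left, s.sim_right = sl, sr
        return s

    def test_retained_and_discarded(self):
        good, bad = self._site(0.9, 0.9), self._site(0.9, 0.4)
        out, _ = filter_sites([good, bad], min_similarity=0.5)
        assert good.status == "conserved"
        assert bad.status == "discarded_low_quality"

    def test_first_quartile_linear_interpolation(self):
        _, q1 = filter_sites([], alignment_similarities=[0.2, 0.4, 0.6, 0.8])
        assert q1 == pytest.approx(0.35)

    def test_junction_confirmation_and_offset_mismatch(self):
        i_ok = intron("A", 6, chrom_id="c1", genomic_start=100, genomic_end=160)
        i_off = intron("A", 9, chrom_id="c1", genomic_start=200, genomic_end=260)
        from intronevo.orthology import IntronSiteCall

        s1 = IntronSiteCall(OrthologPair("A", "B"), 6, 0, "discordant_a_only", intron_a=i_ok)
        s2 = IntronSiteCall(OrthologPair("A", "B"), 9, 0, "discordant_a_only", intron_a=i_off)
        junctions = {("c1", 100, 160): 5, ("c1", 201, 260): 5}  # second off by 1 nt
        junction_filter([s1, s2], junctions)
        assert s1.status == "discordant_a_only"
        assert s2.status == "discarded_junction"

    def test_no_junction_data_retains_sites(self):
        from intronevo.orthology import IntronSiteCall

        s = IntronSiteCall(OrthologPair("A", "B"), 6, 0, "discordant_a_only", intron_a=intron("A", 6))
        out = junction_filter([s], None)
        assert out[0].status == "discordant_a_only"
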