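"""Gene-model construction, validation and intron extraction."""

import pytest

from intronevo.genome_io import (
    build_gene_models,
    extract_introns,
    read_fasta,
    write_gff3,
)

from conftest import write_fasta, write_gff3 as _gff


def gff_gene(chrom, gid, strand, cds_rows):
    lo = min(r[0] for r in cds_rows)
    hi = max(r[1] for r in cds_rows)
    rows = [
        (chrom, "t", "gene", lo, hi, ".", strand, ".", f"ID={gid}"),
        (chrom, "t", "mRNA", lo, hi, ".", strand, ".", f"ID={gid}.1;Parent={gid}"),
    ]
    for s, e in cds_rows:
        rows.append((chrom, "t", "CDS", s, e, ".", strand, "0", f"ID=c;Parent={gid}.1"))
    return rows


class TestReadFasta:
    def test_case_normalization(self, tmp_path):
        p = write_fasta(tmp_path / "a.fa", [("c1", "acgt")])
        recs = read_fasta(p, species_id="SP")
        assert len(recs) == 1 and recs[0].sequence == "ACGT"
        assert recs[0].species_id == "SP"

    def test_duplicate_id_is_error(self, tmp_path):
        p = write_fasta(tmp_path / "a.fa", [("c1", "ACGT"), ("c1", "TTTT")])
        with pytest.raises(ValueError, match="c1"):
            read_fasta(p)

    def test_ambiguity_mapped_to_n(self, tmp_path, caplog):
        p = write_fasta(tmp_path / "a.fa", [("c1", "ACRT")])
        recs = read_fasta(p)
        assert recs[0].sequence == "ACNT"

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            read_fasta(str(p))


class TestBuildGeneModels:
    def test_retained_and_not_mult3(self, tmp_path):
        # g1: 9 bp CDS (clean); g2: 10 bp CDS -> not_mult3
        chrom = "ATGGCTTAA" + "ATGGCTTAAG" + "A" * 20
        fa = write_fasta(tmp_path / "g.fa", [("c1", chrom)])
        rows = gff_gene("c1", "g1", "+", [(1, 9)]) + gff_gene("c1", "g2", "+", [(10, 19)])
        gff = _gff(tmp_path / "g.gff3", rows)
        models, rejects = build_gene_models(gff, read_fasta(fa, species_id="SP"))
        assert [m.gene_id for m in models] == ["g1"]
        assert ("g2", "not_mult3") in rejects

    def test_minus_strand_two_exon_translation(self, tmp_path):
        # transcript: ATG GCT TAA split as exon1=ATGG, exon2=CTTAA... build on - strand
        spliced = "ATGGCTGGTTAA"  # M A G *
        exon1_t, exon2_t = spliced[:5], spliced[5:]  # transcript order
        intron_t = "GTAAACCCAG"

        def rc(s):
            return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]

        # on the chromosome (plus orientation): rc(exon2) + rc(intron) + rc(exon1)
        chrom = "TT" + rc(exon2_t) + rc(intron_t) + rc(exon1_t) + "GG"
        fa = write_fasta(tmp_path / "m.fa", [("c1", chrom)])
        s2 = 3  # 1-based start of rc(exon2)
        e2 = s2 + len(exon2_t) - 1
        s1 = e2 + len(intron_t) + 1
        e1 = s1 + len(exon1_t) - 1
        gff = _gff(tmp_path / "m.gff3", gff_gene("c1", "gm", "-", [(s2, e2), (s1, e1)]))
        models, rejects = build_gene_models(gff, read_fasta(fa, species_id="SP"))
        assert rejects == []
        (m,) = models
        assert m.spliced_cds == spliced
        assert m.protein == "MAG"
        # transcript order: first segment is the genomically later one
        assert m.cds_segments[0][0] > m.cds_segments[1][0]

    def test_unknown_chromosome_rejects_not_crashes(self, tmp_path):
        fa = write_fasta(tmp_path / "g.fa", [("c1", "ATGGCTTAA")])
        gff = _gff(tmp_path / "g.gff3", gff_gene("cX", "g1", "+", [(1, 9)]))
        models, rejects = build_gene_models(gff, read_fasta(fa, species_id="SP"))
        assert models == [] and len(rejects) == 1

    def test_internal_stop_rejected(self, tmp_path):
        fa = write_fasta(tmp_path / "g.fa", [("c1", "ATGTAAGCTTAA")])
        gff = _gff(tmp_path / "g.gff3", gff_gene("c1", "g1", "+", [(1, 12)]))
        _, rejects = build_gene_models(gff, read_fasta(fa, species_id="SP"))
        assert ("g1", "internal_stop") in rejects


class TestExtractIntrons:
    def test_single_exon_gene_has_none(self, tmp_path):
        fa = write_fasta(tmp_path / "g.fa", [("c1", "ATGGCTTAA")])
        gff = _gff(tmp_path / "g.gff3", gff_gene("c1", "g1", "+", [(1, 9)]))
        (m,), _ = build_gene_models(gff, read_fasta(fa, species_id="SP"))
        assert extract_introns(m) == []

    def test_offset_phase_length_arithmetic(self, two_exon_plus_gene):
        (intr,) = extract_introns(two_exon_plus_gene)
        assert intr.cds_offset == 10
        assert intr.phase == 1
        assert intr.length == 120
        assert intr.genomic_start == 10 and intr.genomic_end == 130

    def test_minus_strand_intron_is_revcomp_of_gap(self, tmp_path):
        spliced = "ATGGCTGGTTAA"
        exon1_t, exon2_t = spliced[:6], spliced[6:]
        intron_t = "GTCCATTTAG"

        def rc(s):
            return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]

        chrom = rc(exon2_t) + rc(intron_t) + rc(exon1_t)
        fa = write_fasta(tmp_path / "m.fa", [("c1", chrom)])
        n2, ni, n1 = len(exon2_t), len(intron_t), len(exon1_t)
        gff = _gff(
            tmp_path / "m.gff3",
            gff_gene("c1", "gm", "-", [(1, n2), (n2 + ni + 1, n2 + ni + n1)]),
        )
        (m,), _ = build_gene_models(gff, read_fasta(fa, species_id="SP"))
        (intr,) = extract_introns(m)
        assert intr.sequence == intron_t
        gap = m.chrom_seq[intr.genomic_start : intr.genomic_end]
        assert intr.sequence == rc(gap)


class TestInvariants:
    def test_gff3_round_trip(self, tmp_path, small_clade):
        from intronevo.genome_io import read_fasta as rf

        sp = "DDB"
        genomes = rf(small_clade.fasta[sp], species_id=sp)
        models, _ = build_gene_models(small_clade.gff[sp], genomes)
        out = tmp_path / "roundtrip.gff3"
        write_gff3(models, str(out))
        models2, rejects2 = build_gene_models(str(out), genomes)
        assert rejects2 == []
        by_id = {m.gene_id: m for m in models2}
        for m in models:
            m2 = by_id[m.gene_id]
            assert m2.cds_segments == m.cds_segments and m2.strand == m.strand

    def test_length_conservation_and_phase(self, small_clade):
        from intronevo.genome_io import read_fasta as rf

        sp = "DPU"
        genomes = rf(small_clade.fasta[sp], species_id=sp)
        models, _ = build_gene_models(small_clade.gff[sp], genomes)
        assert models
        for m in models:
            introns = extract_introns(m)
            span = max(e for _, e in m.cds_segments) - min(s for s, _ in m.cds_segments)
            assert sum(i.length for i in introns) + len(m.spliced_cds) == span
            for i in introns:
                assert i.phase == i.cds_offset % 3
                assert i.phase in (0, 1, 2)
                assert 0 < i.cds_offset < len(m.spliced_cds)
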