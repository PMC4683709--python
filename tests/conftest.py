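import pytest

from intronevo.genome_io import GeneModel, GenomeSequence, build_gene_models, extract_introns
from intronevo.synthetic_data import SimulationConfig, simulate_clade


@pytest.fixture
def two_exon_plus_gene():
    """Plus-strand toy: exons [0,10) and [130,160) on a 200 bp chromosome."""
    exon1 = "ATGGCTGCTG"  # 10 bp
    intron = "GT" + "A" * 116 + "AG"  # 120 bp
    exon2 = ("CTG" * 10)[:30]  # 30 bp
    seq = (exon1 + intron + exon2 + "A" * 40)[:200]
    gene = GeneModel(
        gene_id="toy+",
        species_id="SP",
        chrom_id="c1",
        strand="+",
        cds_segments=[(0, 10), (130, 160)],
        spliced_cds=seq[0:10] + seq[130:160],
        protein="",
        chrom_seq=seq,
    )
    return gene


@pytest.fixture(scope="session")
def small_clade(tmp_path_factory):
    """A small simulated clade shared by integration tests."""
    cfg = SimulationConfig(
        seed=11,
        n_genes=40,
        loss_counts={"DDB": 8, "DPU": 4},
        gain_counts={"DDB": 2, "DPU": 2},
    )
    outdir = tmp_path_factory.mktemp("clade")
    return simulate_clade(cfg, str(outdir))


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return str(path)


def write_gff3(path, rows):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return str(path)
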