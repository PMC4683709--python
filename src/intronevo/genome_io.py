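"""Genome and annotation input: validated gene models and intron extraction.

Coordinates are 0-based half-open internally; GFF3 I/O converts from/to the
1-based inclusive convention of the format. A gene model is the spliced CDS of
a single transcript (the longest, if the annotation offers several); UTRs are
ignored throughout.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")

#: reason codes for the rejects report
REJECT_REASONS = ("not_mult3", "bad_translation", "out_of_bounds", "internal_stop")


@dataclass
class GenomeSequence:
    """One chromosome/contig of one species, normalized to ACGTN uppercase."""

    species_id: str
    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.chrom_id}")


@dataclass
class GeneModel:
    """A protein-coding gene: ordered CDS segments and the spliced product.

    ``cds_segments`` are [start, end) intervals in chromosome coordinates,
    listed in transcription (5'->3' of the transcript) order; for minus-strand
    genes that means descending genomic position.
    """

    gene_id: str
    species_id: str
    chrom_id: str
    strand: str
    cds_segments: list[tuple[int, int]]
    spliced_cds: str
    protein: str
    chrom_seq: str = field(repr=False, default="")

    @property
    def n_introns(self) -> int:
        return len(self.cds_segments) - 1


@dataclass
class Intron:
    """An intron located between two CDS segments of a gene model.

    ``cds_offset`` counts spliced-CDS nucleotides upstream of the intron;
    ``phase`` is that offset mod 3. ``sequence`` is in transcript orientation.
    Genomic coordinates (0-based half-open) are kept for junction matching.
    """

    gene_id: str
    ordinal: int
    cds_offset: int
    phase: int
    length: int
    sequence: str
    chrom_id: str = ""
    genomic_start: int = 0
    genomic_end: int = 0

    @property
    def donor2(self) -> str:
        return self.sequence[:2]

    @property
    def acceptor2(self) -> str:
        return self.sequence[-2:]


def _normalize(seq: str, record_id: str) -> str:
    seq = seq.upper()
    if set(seq) <= _VALID:
        return seq
    cleaned = []
    n_mapped = 0
    for base in seq:
        if base in _VALID:
            cleaned.append(base)
        else:
            cleaned.append("N")
            n_mapped += 1
    logger.warning("%s: mapped %d ambiguity bases to N", record_id, n_mapped)
    return "".join(cleaned)


def read_fasta(path: str, species_id: str | None = None) -> list[GenomeSequence]:
    """Read a genome FASTA into :class:`GenomeSequence` records.

    Sequences are upper-cased; IUPAC ambiguity codes other than N are mapped
    to N with a warning. Duplicate identifiers and empty files are errors.
    If ``species_id`` is not given, the file stem is used.
    """
    if species_id is None:
        species_id = os.path.splitext(os.path.basename(path))[0]
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence identifier: {rec.id}")
        seen.add(rec.id)
        records.append(GenomeSequence(species_id, rec.id, _normalize(str(rec.seq), rec.id)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _segments_for_mrna(db: gffutils.FeatureDB, mrna) -> list[tuple[int, int]]:
    segs = []
    for cds in db.children(mrna, featuretype="CDS", order_by="start"):
        segs.append((cds.start - 1, cds.end))  # GFF3 1-based inclusive -> half-open
    return segs


def build_gene_models(
    gff3_path: str, genomes: list[GenomeSequence]
) -> tuple[list[GeneModel], list[tuple[str, str]]]:
    """Build validated gene models from a GFF3 annotation.

    One model per gene is retained (the mRNA with the longest spliced CDS when
    several are annotated). Genes failing validation are excluded and reported
    as ``(gene_id, reason)`` with reasons in :data:`REJECT_REASONS`; a CDS on
    an unknown chromosome rejects the gene rather than raising.

    Returns ``(models, rejects)``.
    """
    chrom = {g.chrom_id: g for g in genomes}
    species = genomes[0].species_id if genomes else ""
    db = gffutils.create_db(
        gff3_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    rejects: list[tuple[str, str]] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            continue
        candidates = []
        for m in mrnas:
            segs = _segments_for_mrna(db, m)
            if segs:
                candidates.append((sum(e - s for s, e in segs), segs, m))
        if not candidates:
            continue
        _, segs, mrna = max(candidates, key=lambda t: t[0])
        model, reason = _validate_gene(gene.id, species, gene.seqid, gene.strand, segs, chrom)
        if model is not None:
            models.append(model)
        else:
            rejects.append((gene.id, reason))
            logger.info("rejected gene %s: %s", gene.id, reason)
    return models, rejects


def _validate_gene(
    gene_id: str,
    species: str,
    chrom_id: str,
    strand: str,
    segs: list[tuple[int, int]],
    chrom: dict[str, GenomeSequence],
) -> tuple[GeneModel | None, str]:
    if chrom_id not in chrom:
        return None, "out_of_bounds"
    seq = chrom[chrom_id].sequence
    segs = sorted(segs)
    for i, (s, e) in enumerate(segs):
        if s < 0 or e > len(seq) or s >= e:
            return None, "out_of_bounds"
        if i and s < segs[i - 1][1]:
            return None, "out_of_bounds"  # overlapping CDS segments
    spliced = "".join(seq[s:e] for s, e in segs)
    if strand == "-":
        spliced = _revcomp(spliced)
        segs = segs[::-1]  # transcription order
    if len(spliced) % 3 != 0:
        return None, "not_mult3"
    aa = str(Seq(spliced).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        return None, "internal_stop"
    if "X" in aa and "N" not in spliced:
        return None, "bad_translation"
    return (
        GeneModel(gene_id, species, chrom_id, strand, segs, spliced, aa, chrom_seq=seq),
        "",
    )


def extract_introns(gene: GeneModel) -> list[Intron]:
    """Derive the introns of a gene model from gaps between CDS segments.

    Offsets accumulate spliced lengths of upstream segments; intron sequence
    is taken from the genomic gap in transcript orientation.
    """
    introns: list[Intron] = []
    offset = 0
    for i in range(len(gene.cds_segments) - 1):
        a = gene.cds_segments[i]
        b = gene.cds_segments[i + 1]
        offset += a[1] - a[0]
        if gene.strand == "+":
            gstart, gend = a[1], b[0]
        else:
            gstart, gend = b[1], a[0]
        if gend <= gstart:
            raise ValueError(f"overlapping CDS segments in gene {gene.gene_id}")
        seq = gene.chrom_seq[gstart:gend] if gene.chrom_seq else ""
        if gene.strand == "-":
            seq = _revcomp(seq)
        introns.append(
            Intron(
                gene_id=gene.gene_id,
                ordinal=i + 1,
                cds_offset=offset,
                phase=offset % 3,
                length=gend - gstart,
                sequence=seq,
                chrom_id=gene.chrom_id,
                genomic_start=gstart,
                genomic_end=gend,
            )
        )
    return introns


def write_gff3(models: list[GeneModel], path: str) -> None:
    """Write retained gene models back to GFF3 (gene/mRNA/CDS rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            segs = sorted(g.cds_segments)
            lo, hi = segs[0][0] + 1, segs[-1][1]
            fh.write(
                f"{g.chrom_id}\tintronevo\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom_id}\tintronevo\tmRNA\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for s, e in segs:
                fh.write(
                    f"{g.chrom_id}\tintronevo\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID=cds-{mrna_id};Parent={mrna_id}\n"
                )


def write_rejects(rejects: list[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\treason\n")
        for gid, reason in rejects:
            fh.write(f"{gid}\t{reason}\n")
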