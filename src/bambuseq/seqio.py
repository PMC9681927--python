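"""Sequence, gene-model and table I/O.

This module is the single source of truth for coordinate conventions:
internally every interval is 0-based half-open; GFF3's 1-based inclusive
coordinates are converted exactly once, at the read/write boundary.
All transcript-level analyses operate in transcription orientation;
genomic intervals retain scaffold orientation.
"""
from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

DNA_ALPHABET = set("ACGTN")
STOP_CODONS = {"TAA", "TAG", "TGA"}
# IUPAC ambiguity codes other than N are collapsed to N (exact-match gap
# filling downstream needs the small alphabet).
_AMBIGUOUS = set("RYSWKMBDHV")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(cds: str) -> str:
    """Standard-code translation; trailing partial codon ignored."""
    n = len(cds) - len(cds) % 3
    return str(Seq(cds[:n]).translate())


@dataclass
class SequenceRecord:
    """One named sequence (DNA or protein)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be nonempty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be nonempty")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)


def sanitize_dna(record: SequenceRecord) -> SequenceRecord:
    """Map non-N IUPAC ambiguity codes to N (with a warning)."""
    residues = record.residues
    bad = set(residues) & _AMBIGUOUS
    if bad:
        warnings.warn(
            f"record {record.id!r}: ambiguity codes {sorted(bad)} mapped to N"
        )
        table = str.maketrans({c: "N" for c in _AMBIGUOUS})
        residues = residues.translate(table)
    unknown = set(residues) - DNA_ALPHABET
    if unknown:
        raise ValueError(
            f"record {record.id!r}: non-DNA characters {sorted(unknown)}"
        )
    return SequenceRecord(record.id, residues, record.description)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a scaffold."""

    scaffold: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def gff_to_internal(start1: int, end1: int) -> tuple[int, int]:
    """GFF3 1-based inclusive -> internal 0-based half-open."""
    return start1 - 1, end1


def internal_to_gff(start0: int, end0: int) -> tuple[int, int]:
    """Internal 0-based half-open -> GFF3 1-based inclusive."""
    return start0 + 1, end0


@dataclass
class GeneModel:
    """A reference gene: ordered exons on a scaffold, derived CDS and peptide.

    Exons are sorted 5'->3' in *transcription* order (descending genomic
    coordinates on the minus strand); the CDS is the exon concatenation in
    that order, reverse-complemented for minus-strand genes.
    """

    gene_id: str
    scaffold: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds: SequenceRecord
    peptide: SequenceRecord
    flags: tuple[str, ...] = ()

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(len(e) for e in self.exons)

    @property
    def cds_junctions(self) -> tuple[int, ...]:
        """CDS coordinates of exon-exon junctions (start of exon i+1)."""
        out, acc = [], 0
        for ln in self.exon_lengths[:-1]:
            acc += ln
            out.append(acc)
        return tuple(out)

    @property
    def intron_lengths(self) -> tuple[int, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append(b.start - a.end)
            else:
                out.append(a.start - b.end)
        return tuple(out)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append(GenomicInterval(self.scaffold, a.end, b.start, "+"))
            else:
                out.append(GenomicInterval(self.scaffold, b.end, a.start, "-"))
        return tuple(out)

    def validate(self) -> None:
        ivals = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ivals, ivals[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        if len(self.cds.residues) != sum(self.exon_lengths):
            raise ValueError(f"gene {self.gene_id}: CDS length != exon sum")
        if len(self.cds.residues) % 3 == 0:
            pep = translate(self.cds.residues)
            if not pep.endswith("*") or "*" in pep[:-1]:
                raise ValueError(
                    f"gene {self.gene_id}: CDS must end with a single stop"
                )
            if pep[:-1] != self.peptide.residues:
                raise ValueError(f"gene {self.gene_id}: peptide != translate(cds)")


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[SequenceRecord]:
    with _open(path) as fh:
        records = [
            SequenceRecord(r.id, str(r.seq), _description_of(r))
            for r in SeqIO.parse(fh, "fasta")
        ]
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    _check_unique_ids(records, path)
    return records


def _description_of(rec: _BioRecord) -> str:
    desc = rec.description
    if desc.startswith(rec.id):
        desc = desc[len(rec.id):].strip()
    return desc


def _check_unique_ids(records: Sequence[SequenceRecord], path) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {r.id!r}")
        seen.add(r.id)


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with _open(path, "wt") as fh:
        for r in records:
            header = f">{r.id} {r.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i : i + width] + "\n")


def read_fastq(path) -> list[SequenceRecord]:
    with _open(path) as fh:
        records = [
            SequenceRecord(r.id, str(r.seq), _description_of(r))
            for r in SeqIO.parse(fh, "fastq")
        ]
    if not records:
        raise ValueError(f"{path}: empty or not FASTQ")
    return records


def write_fastq(records: Iterable[SequenceRecord], path, qual_char: str = "I") -> None:
    with _open(path, "wt") as fh:
        for r in records:
            fh.write(f"@{r.id}\n{r.residues}\n+\n{qual_char * len(r.residues)}\n")


# ---------------------------------------------------------------------------
# GFF3 gene models

def read_gene_models(gff_path, genome_fasta_path) -> list[GeneModel]:
    """Read gene/mRNA/exon GFF3 plus scaffold FASTA into GeneModels.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Minus-strand exons are ordered in transcription order and the CDS is
    the reverse complement of the genomic exon concatenation.  A CDS whose
    length is not divisible by 3 is flagged, not dropped.
    """
    genome = {r.id: sanitize_dna(r).residues for r in read_fasta(genome_fasta_path)}
    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA")) or [gene]
        mrna = mrnas[0]
        exon_feats = list(db.children(mrna, featuretype="exon"))
        if not exon_feats:
            exon_feats = list(db.children(mrna, featuretype="CDS"))
        if not exon_feats:
            continue
        strand = gene.strand if gene.strand in "+-" else "+"
        exons = []
        for f in sorted(exon_feats, key=lambda f: f.start):
            if f.seqid not in genome:
                raise ValueError(
                    f"gene {gene.id}: exon references missing scaffold {f.seqid!r}"
                )
            s0, e0 = gff_to_internal(f.start, f.end)
            exons.append(GenomicInterval(f.seqid, s0, e0, strand))
        scaffold_seq = genome[exons[0].scaffold]
        # concatenate in ascending genomic order; the reverse complement of
        # that concatenation is the minus-strand transcript
        cds_seq = "".join(scaffold_seq[e.start : e.end] for e in exons)
        if strand == "-":
            cds_seq = revcomp(cds_seq)
            exons = exons[::-1]  # transcription order
        flags: tuple[str, ...] = ()
        if len(cds_seq) % 3 != 0:
            warnings.warn(f"gene {gene.id}: CDS length not divisible by 3")
            flags = ("cds_not_multiple_of_3",)
            pep = translate(cds_seq)
        else:
            pep = translate(cds_seq)
        pep = pep[:-1] if pep.endswith("*") else pep
        model = GeneModel(
            gene_id=gene.id,
            scaffold=exons[0].scaffold,
            strand=strand,
            exons=tuple(exons),
            cds=SequenceRecord(gene.id + ".cds", cds_seq),
            peptide=SequenceRecord(gene.id + ".pep", pep or "X"),
            flags=flags,
        )
        if not flags:
            model.validate()
        models.append(model)
    return models


def write_gene_models(models: Sequence[GeneModel], gff_path) -> None:
    """Emit gene/mRNA/exon rows in GFF3 (1-based inclusive)."""
    with _open(gff_path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = (min(e.start for e in m.exons), max(e.end for e in m.exons))
            g1, g2 = internal_to_gff(*span)
            fh.write(
                f"{m.scaffold}\tbambuseq\tgene\t{g1}\t{g2}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            fh.write(
                f"{m.scaffold}\tbambuseq\tmRNA\t{g1}\t{g2}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}.t1;Parent={m.gene_id}\n"
            )
            for i, e in enumerate(sorted(m.exons, key=lambda e: e.start), 1):
                s1, e1 = internal_to_gff(e.start, e.end)
                fh.write(
                    f"{m.scaffold}\tbambuseq\texon\t{s1}\t{e1}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id}.exon{i};Parent={m.gene_id}.t1\n"
                )


# ---------------------------------------------------------------------------
# Tables

def read_counts(path):
    """Read a gene x library TSV of integer counts into a CountMatrix."""
    from .expression import CountMatrix  # local import avoids a cycle

    lines = Path(path).read_text().rstrip("\n").split("\n")
    if not lines or not lines[0]:
        raise ValueError(f"{path}: empty counts file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ValueError(f"{path}: missing header or no library columns")
    libraries = header[1:]
    for lib in libraries:
        if _looks_numeric(lib):
            raise ValueError(f"{path}: missing header (numeric column name {lib!r})")
    genes, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ValueError(
                f"{path}: line {lineno}: expected {len(header)} columns, "
                f"got {len(cells)}"
            )
        genes.append(cells[0])
        row = []
        for lib, cell in zip(libraries, cells[1:]):
            try:
                v = int(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer count {cell!r} "
                    f"in library {lib}"
                ) from None
            if v < 0:
                raise ValueError(f"{path}: line {lineno}: negative count {v}")
            row.append(v)
        rows.append(row)
    import numpy as np

    return CountMatrix(genes=genes, libraries=libraries, counts=np.array(rows, int))


def _looks_numeric(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_counts(cm, path) -> None:
    with _open(path, "wt") as fh:
        fh.write("gene\t" + "\t".join(cm.libraries) + "\n")
        for g, row in zip(cm.genes, cm.counts):
            fh.write(g + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_orthogroups(path) -> dict[str, str]:
    """Two-column TSV: contig id -> orthogroup id."""
    out: dict[str, str] = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            out[cells[0]] = cells[1]
    return out


def write_orthogroups(mapping: dict[str, str], path) -> None:
    with _open(path, "wt") as fh:
        for k, v in mapping.items():
            fh.write(f"{k}\t{v}\n")


def read_ct_table(path):
    """Long-format qPCR table: sample <TAB> gene <TAB> ct (one technical rep per row)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"sample", "gene", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: CT table needs columns {sorted(required)}")
    return df
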