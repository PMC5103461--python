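"""Readers, writers and validated domain types for the standard formats.

All coordinates are 0-based half-open internally; conversion to the 1-based
closed convention of GFF3 happens only at the format boundary.  Sequences are
stored uppercase; IUPAC ambiguity codes are accepted on input but treated as
uncallable (like ``N``) by every downstream analysis.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

DNA_STRICT = set("ACGTN")
IUPAC_AMBIGUITY = set("RYSWKMBDHV")
DNA_ALPHABET = DNA_STRICT | IUPAC_AMBIGUITY

#: columns of the conventional 12-column tabular similarity-search format
HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


class FormatError(ValueError):
    """Malformed file or record violating a format/domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A named nucleotide sequence (scaffold, bait, contig...)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid sequence id {self.id!r}")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} is empty")
        self.residues = self.residues.upper()
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise FormatError(
                f"sequence {self.id!r}: illegal character "
                f"{self.residues[pos]!r} at offset {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)


class GenomeAssembly:
    """Ordered collection of :class:`SequenceRecord` with unique ids."""

    def __init__(self, records: Iterable[SequenceRecord]):
        self.records: list[SequenceRecord] = list(records)
        self._index: dict[str, SequenceRecord] = {}
        for rec in self.records:
            if rec.id in self._index:
                raise FormatError(f"duplicate sequence id {rec.id!r}")
            self._index[rec.id] = rec

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        return self._index[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)


@dataclass
class ReadRecord:
    """A sequencing read with Phred quality scores."""

    id: str
    bases: str
    quals: Sequence[int]

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        if len(self.bases) != len(self.quals):
            raise FormatError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        bad = set(self.bases) - DNA_STRICT
        if bad:
            raise FormatError(f"read {self.id!r}: illegal characters {bad}")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class GeneModel:
    """A protein-coding gene as an ordered set of CDS exons.

    ``cds_exons`` are 0-based half-open intervals on the forward strand,
    sorted by coordinate; reverse-strand genes carry ``strand='-'`` and are
    reverse-complemented at spliced-CDS extraction time.
    """

    gene_id: str
    scaffold: str
    strand: str
    cds_exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if not self.cds_exons:
            raise FormatError(f"gene {self.gene_id!r}: no CDS exons")
        prev_end = -1
        for start, end in self.cds_exons:
            if start >= end:
                raise FormatError(
                    f"gene {self.gene_id!r}: empty/inverted exon [{start},{end})"
                )
            if start < prev_end:
                raise FormatError(
                    f"gene {self.gene_id!r}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_exons[0][0], self.cds_exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.cds_exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Inter-exon gaps (0-based half-open), in forward-strand order."""
        return [
            (self.cds_exons[i][1], self.cds_exons[i + 1][0])
            for i in range(len(self.cds_exons) - 1)
        ]

    def spliced_cds(self, assembly: GenomeAssembly) -> str:
        if self.scaffold not in assembly:
            raise FormatError(
                f"gene {self.gene_id!r}: scaffold {self.scaffold!r} not in assembly"
            )
        seq = assembly[self.scaffold].residues
        if self.span[1] > len(seq):
            raise FormatError(f"gene {self.gene_id!r}: exceeds scaffold bounds")
        cds = "".join(seq[s:e] for s, e in self.cds_exons)
        if self.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds


@dataclass
class AlignmentBlock:
    """One gapped pairwise alignment block (reference row + query row)."""

    ref_id: str
    ref_start: int
    query_id: str
    query_start: int
    strand: str
    ref_text: str
    query_text: str

    def __post_init__(self) -> None:
        if len(self.ref_text) != len(self.query_text):
            raise FormatError(
                f"block {self.ref_id}/{self.query_id}: ragged rows "
                f"({len(self.ref_text)} vs {len(self.query_text)} columns)"
            )
        self.ref_text = self.ref_text.upper()
        self.query_text = self.query_text.upper()
        for i, (a, b) in enumerate(zip(self.ref_text, self.query_text)):
            if a == "-" and b == "-":
                raise FormatError(
                    f"block {self.ref_id}/{self.query_id}: all-gap column {i}"
                )

    @property
    def n_columns(self) -> int:
        return len(self.ref_text)

    @property
    def ref_span(self) -> tuple[int, int]:
        n = sum(1 for c in self.ref_text if c != "-")
        return self.ref_start, self.ref_start + n


@dataclass
class HitRecord:
    """One row of a 12-column tabular similarity-search result."""

    query: str
    subject: str
    pct_identity: float
    aln_length: int
    mismatch: int = 0
    gapopen: int = 0
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0
    evalue: float = 0.0
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise FormatError(f"hit {self.query}->{self.subject}: pident out of range")
        if self.aln_length < 1:
            raise FormatError(f"hit {self.query}->{self.subject}: aln_length < 1")
        if self.evalue < 0:
            raise FormatError(f"hit {self.query}->{self.subject}: negative e-value")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read a FASTA file into a validated :class:`GenomeAssembly`."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq), description=rec.description)
        )
    return GenomeAssembly(records)


def write_fasta(assembly: GenomeAssembly | Iterable[SequenceRecord],
                path: str | Path, wrap: int = 60) -> None:
    records = assembly.records if isinstance(assembly, GenomeAssembly) else list(assembly)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id \
                else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i:i + wrap] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (Phred+33)
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> list[ReadRecord]:
    reads: list[ReadRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            reads.append(
                ReadRecord(
                    id=rec.id,
                    bases=str(rec.seq),
                    quals=list(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:
        raise FormatError(
            f"malformed FASTQ record at index {len(reads)}: {exc}"
        ) from exc
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quals)
            fh.write(f"@{read.id}\n{read.bases}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GFF3 (gene / mRNA / CDS)
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (1-based closed on disk -> 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        cds_list = list(db.children(gene, featuretype="CDS", order_by="start"))
        if not cds_list:
            continue
        exons = []
        for cds in cds_list:
            if cds.start > cds.end:
                raise FormatError(f"feature {cds.id}: start > end")
            if cds.start < gene.start or cds.end > gene.end:
                raise FormatError(
                    f"feature {cds.id}: CDS outside parent gene {gene.id}"
                )
            exons.append((cds.start - 1, cds.end))
        models.append(
            GeneModel(
                gene_id=gene.id, scaffold=gene.seqid,
                strand=gene.strand, cds_exons=sorted(exons),
            )
        )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path,
               source: str = "straindiverge") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start, end = m.span
            fh.write(
                f"{m.scaffold}\t{source}\tgene\t{start + 1}\t{end}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id}\n"
            )
            mrna_id = f"{m.gene_id}.t1"
            fh.write(
                f"{m.scaffold}\t{source}\tmRNA\t{start + 1}\t{end}\t.\t"
                f"{m.strand}\t.\tID={mrna_id};Parent={m.gene_id}\n"
            )
            # CDS phase tracks spliced frame in transcription order
            order = m.cds_exons if m.strand == "+" else m.cds_exons[::-1]
            phase, rows = 0, []
            for s, e in order:
                rows.append((s, e, phase))
                phase = (3 - ((e - s) - phase) % 3) % 3
            for s, e, ph in sorted(rows):
                fh.write(
                    f"{m.scaffold}\t{source}\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{m.strand}\t{ph}\tID={mrna_id}.cds;Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# MAF import (bypass for externally produced pairwise alignments)
# ---------------------------------------------------------------------------

def read_maf(path: str | Path) -> list[AlignmentBlock]:
    blocks: list[AlignmentBlock] = []
    try:
        for aln in AlignIO.parse(str(path), "maf"):
            if len(aln) != 2:
                raise FormatError(
                    f"MAF block {len(blocks)}: expected 2 rows, got {len(aln)}"
                )
            ref, qry = aln[0], aln[1]
            strand = "+" if qry.annotations.get("strand", 1) == 1 else "-"
            blocks.append(
                AlignmentBlock(
                    ref_id=ref.id, ref_start=int(ref.annotations["start"]),
                    query_id=qry.id, query_start=int(qry.annotations["start"]),
                    strand=strand,
                    ref_text=str(ref.seq), query_text=str(qry.seq),
                )
            )
    except ValueError as exc:
        raise FormatError(f"malformed MAF near block {len(blocks)}: {exc}") from exc
    return blocks


def write_maf(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for b in blocks:
            ref_len = sum(1 for c in b.ref_text if c != "-")
            qry_len = sum(1 for c in b.query_text if c != "-")
            fh.write("a\n")
            fh.write(f"s {b.ref_id} {b.ref_start} {ref_len} + 0 {b.ref_text}\n")
            fh.write(f"s {b.query_id} {b.query_start} {qry_len} {b.strand} 0 "
                     f"{b.query_text}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# 12-column tabular hit format
# ---------------------------------------------------------------------------

def read_hits_tab(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tab-separated hit table (blast -outfmt 6 layout)."""
    text = Path(path).read_text()
    if not text.strip():
        return []
    try:
        df = pd.read_csv(
            io.StringIO(text), sep="\t", header=None, names=HIT_COLUMNS,
            comment="#", float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:
        raise FormatError(f"ragged hit table {path}: {exc}") from exc
    if df.shape[1] != 12 or df[HIT_COLUMNS[-1]].isna().any():
        bad = int(df.index[df[HIT_COLUMNS[-1]].isna()][0]) + 1 \
            if df[HIT_COLUMNS[-1]].isna().any() else 1
        raise FormatError(f"hit table {path}: wrong column count at line {bad}")
    return [
        HitRecord(
            query=str(r.qseqid), subject=str(r.sseqid),
            pct_identity=float(r.pident), aln_length=int(r.length),
            mismatch=int(r.mismatch), gapopen=int(r.gapopen),
            qstart=int(r.qstart), qend=int(r.qend),
            sstart=int(r.sstart), send=int(r.send),
            evalue=float(r.evalue), bitscore=float(r.bitscore),
        )
        for r in df.itertuples()
    ]


def write_hits_tab(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t{h.pct_identity:.2f}\t{h.aln_length}\t"
                f"{h.mismatch}\t{h.gapopen}\t{h.qstart}\t{h.qend}\t{h.sstart}\t"
                f"{h.send}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


def hits_to_frame(hits: Sequence[HitRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "query": [h.query for h in hits],
            "subject": [h.subject for h in hits],
            "pct_identity": [h.pct_identity for h in hits],
            "aln_length": [h.aln_length for h in hits],
            "evalue": [h.evalue for h in hits],
            "bitscore": [h.bitscore for h in hits],
        }
    )
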