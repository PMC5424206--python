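"""Readers and writers for the plain-text formats the pipeline touches.

FASTA (proteins, contigs, tRNAs), GFF3 (gene annotations, 1-based inclusive
coordinates), a two-column depth TSV (contig_id, mean_depth) and Newick
trees.  No science lives here: every function either parses, validates or
serializes.

Conventions
-----------
* Coordinates are 1-based inclusive everywhere (GFF3 convention).
* Sequences are upper-cased on read.  Protein records may use the 20
  standard amino acids plus ``X``; nucleotide records ``ACGT`` plus ``N``.
  Other ambiguity codes are rejected rather than silently remapped.
* Depth is supplied separately from the contig FASTA because FASTA carries
  no coverage; the TSV mirrors common assembler summary outputs without
  binding to one assembler's header dialect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .tree import Tree, format_newick, parse_newick

AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised for malformed input files; the message names the offender."""


@dataclass(frozen=True)
class SeqRecord:
    """One FASTA record: a whitespace-free id, free-text description, residues."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid record id {self.id!r}")
        if not self.residues:
            raise FormatError(f"empty sequence for record {self.id!r}")
        bad = set(self.residues) - (AMINO_ALPHABET | NUCLEOTIDE_ALPHABET)
        if bad:
            raise FormatError(
                f"record {self.id!r} contains characters outside the amino-acid"
                f"/nucleotide alphabets: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FeatureRow:
    """One GFF3 feature; ``attributes`` holds the parsed key=value map."""

    contig_id: str
    source: str
    feature_type: str
    start: int
    end: int
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"feature on {self.contig_id}: start/end {self.start}..{self.end} "
                "violate 1 <= start <= end"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"feature on {self.contig_id}: unknown strand {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DepthRow:
    contig_id: str
    mean_depth: float

    def __post_init__(self):
        if self.mean_depth < 0:
            raise FormatError(f"negative depth for contig {self.contig_id!r}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read FASTA records in file order, upper-casing residues.

    Raises :class:`FormatError` on duplicate ids or empty sequences, naming
    the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        description = rec.description[len(rec.id):].strip()
        records.append(
            SeqRecord(id=rec.id, residues=str(rec.seq).upper(), description=description)
        )
    return records


def read_alignment_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    """Read an aligned FASTA (gap characters allowed) as (ids, rows)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        row = str(rec.seq).upper()
        bad = set(row) - (AMINO_ALPHABET | NUCLEOTIDE_ALPHABET | {"-"})
        if bad:
            raise FormatError(
                f"record {rec.id!r} contains invalid characters: {sorted(bad)}"
            )
        ids.append(rec.id)
        rows.append(row)
    if rows and len({len(r) for r in rows}) != 1:
        raise FormatError(f"{path}: alignment rows differ in length")
    return ids, rows


def write_fasta(records: list[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            raise FormatError(f"malformed attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        out[key] = value
    return out


def read_gff3(path: str | Path) -> list[FeatureRow]:
    """Parse a GFF3 file into :class:`FeatureRow` objects.

    Comment and directive lines are skipped; coordinates stay 1-based
    inclusive; attributes are parsed into an ordered dict.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[FeatureRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            contig, source, ftype, start, end, _score, strand, _phase, attrs = fields
            rows.append(
                FeatureRow(
                    contig_id=contig,
                    source=source,
                    feature_type=ftype,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    attributes=_parse_attributes(attrs),
                )
            )
    return rows


def write_gff3(rows: list[FeatureRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in rows:
            attrs = ";".join(f"{k}={v}" for k, v in row.attributes.items())
            fh.write(
                f"{row.contig_id}\t{row.source}\t{row.feature_type}\t"
                f"{row.start}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Depth TSV


def read_depth_table(path: str | Path) -> list[DepthRow]:
    """Read the two-column (contig_id, mean_depth) TSV; one row per contig."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[DepthRow] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            cid, depth = fields
            if cid == "contig_id":  # optional header
                continue
            if cid in seen:
                raise FormatError(f"duplicate depth row for contig {cid!r}")
            seen.add(cid)
            rows.append(DepthRow(contig_id=cid, mean_depth=float(depth)))
    return rows


def write_depth_table(rows: list[DepthRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tmean_depth\n")
        for row in rows:
            fh.write(f"{row.contig_id}\t{row.mean_depth:.6g}\n")


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: Tree) -> str:
    """Serialize a tree to a Newick string (round-trips via read_newick)."""
    return format_newick(tree)


def read_newick(text_or_path: str | Path) -> Tree:
    """Parse Newick from a string or a file path."""
    if isinstance(text_or_path, Path) or (
        isinstance(text_or_path, str)
        and "\n" not in text_or_path
        and not text_or_path.strip().endswith(";")
        and Path(text_or_path).exists()
    ):
        text = Path(text_or_path).read_text()
    else:
        text = str(text_or_path)
    return parse_newick(text)
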