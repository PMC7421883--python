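"""On-disk formats: protein FASTA, GFF3 gene features, taxonomy tables.

Coordinates follow the GFF3 convention throughout the package: 1-based,
inclusive at both ends.  All tabular outputs are TSV with a header row.
"""
from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

from .errors import ParseError, ValidationError

# 20 standard residues plus X (unknown).  X never counts as a match in any
# identity or distance computation downstream.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")

STRANDS = ("+", "-")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its provenance."""

    id: str
    sequence: str
    source_assembly: str = ""
    taxon: Optional[tuple[str, str]] = None  # (genus, species)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record requires a non-empty id")
        if not self.sequence:
            raise ValidationError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValidationError(
                f"protein {self.id!r}: illegal residue(s) {sorted(bad)!r}; "
                "allowed are the 20 standard amino acids plus X"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """A gene locus on a contig, linked to its protein product."""

    gene_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str
    protein_id: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValidationError(
                f"gene {self.gene_id!r}: coordinates must be positive "
                f"(got {self.start}..{self.end})"
            )
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id!r}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(
                f"gene {self.gene_id!r}: unknown strand {self.strand!r}"
            )

    @property
    def sort_key(self) -> tuple:
        return (self.contig, self.start, self.end, self.gene_id)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, source_assembly: str = "",
               taxon: Optional[tuple[str, str]] = None) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the record id;
    sequences are uppercased.  Raises :class:`ParseError` for a sequence
    line appearing before any header (with its line number) and
    :class:`ValidationError` for duplicate ids.
    """
    path = Path(path)
    text = path.read_text()
    # Pre-scan: Biopython silently ignores junk before the first '>', but the
    # format contract here demands a line-numbered error.
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise ParseError(
                f"{path}:{lineno}: sequence data before first FASTA header"
            )
        break
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                source_assembly=source_assembly,
                taxon=taxon,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_TYPES = {"gene", "mRNA"}


def _parse_attributes(col: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in col.strip().split(";"):
        item = item.strip()
        if not item or "=" not in item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff3(path, protein_id_attr: str = "protein_id") -> list[GeneFeature]:
    """Read gene/mRNA features from a GFF3 file.

    1-based inclusive coordinates are preserved.  ``protein_id`` is taken
    from `protein_id_attr`, falling back to the ``ID`` attribute.  Output is
    sorted by (contig, start, end, gene_id).
    """
    path = Path(path)
    feats: list[GeneFeature] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            contig, _src, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols
            if ftype not in _GFF_TYPES:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            attrs = _parse_attributes(attrs_s)
            gene_id = attrs.get("ID")
            if not gene_id:
                raise ParseError(f"{path}:{lineno}: feature lacks an ID attribute")
            protein_id = attrs.get(protein_id_attr) or gene_id
            try:
                feats.append(
                    GeneFeature(gene_id=gene_id, contig=contig, start=start,
                                end=end, strand=strand, protein_id=protein_id)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    feats.sort(key=lambda f: f.sort_key)
    return feats


def write_gff3(features: Iterable[GeneFeature], path,
               source: str = "pksnrps") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(features, key=lambda f: f.sort_key):
            attrs = f"ID={f.gene_id};protein_id={f.protein_id}"
            fh.write(
                f"{f.contig}\t{source}\tgene\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Taxonomy table (assembly -> genus, species)
# ---------------------------------------------------------------------------

def read_taxonomy(path) -> dict[str, tuple[str, str]]:
    """Read a TSV with columns assembly, genus, species (header required)."""
    path = Path(path)
    out: dict[str, tuple[str, str]] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["assembly", "genus", "species"]:
            raise ParseError(
                f"{path}: expected header 'assembly\\tgenus\\tspecies', "
                f"got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            out[cols[0]] = (cols[1], cols[2])
    return out


def write_taxonomy(taxa: dict[str, tuple[str, str]], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("assembly\tgenus\tspecies\n")
        for asm in sorted(taxa):
            genus, species = taxa[asm]
            fh.write(f"{asm}\t{genus}\t{species}\n")
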