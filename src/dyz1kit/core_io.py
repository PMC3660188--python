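"""Sequence records, 1-based regions, and FASTA / alignment / table IO.

Every module in the toolkit addresses sequences the way the primer and
coordinate tables of the source data do: 1-based, inclusive at both ends,
on the forward strand.  Reverse-strand regions are extracted as the
reverse complement of the forward-strand slice.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

__all__ = [
    "IUPAC_DNA",
    "SequenceRecord",
    "Region",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "extract_region",
    "reverse_complement",
    "read_alignment",
    "GappedRecord",
    "read_table",
]


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (bad header or illegal residue)."""


def _validate_residues(residues: str, context: str = "") -> str:
    residues = residues.upper()
    bad = set(residues) - IUPAC_DNA
    if bad:
        where = f" in {context}" if context else ""
        raise FastaParseError(
            f"illegal residue(s) {sorted(bad)}{where}; "
            "only IUPAC DNA letters are accepted"
        )
    return residues


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """An identified DNA sequence (uppercase IUPAC alphabet)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residues", _validate_residues(self.residues, f"record {self.id!r}")
        )
        if not self.residues:
            raise ValueError(f"record {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclasses.dataclass(frozen=True)
class Region:
    """1-based inclusive coordinate interval with a strand."""

    start: int
    end: int
    strand: str = "forward"

    def __post_init__(self) -> None:
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"strand must be forward|reverse, got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"require 1 <= start <= end, got {self.start}..{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file, preserving record order.

    Residues are uppercased; an empty record or a residue outside the
    IUPAC DNA alphabet raises :class:`FastaParseError` naming the line.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise FastaParseError(f"{path}: line 1: expected FASTA header '>'")
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        residues = str(rec.seq)
        desc = "" if rec.description == rec.id else rec.description
        try:
            records.append(
                SequenceRecord(id=rec.id, residues=residues, description=desc)
            )
        except ValueError as exc:
            raise FastaParseError(
                f"{path}: near line {_find_bad_line(text, rec.id)}: {exc}"
            ) from exc
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def _find_bad_line(text: str, rec_id: str) -> int:
    """Best-effort line number of the first illegal residue after a header."""
    in_record = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">"):
            in_record = line[1:].split()[0] == rec_id if line[1:].split() else False
            continue
        if in_record:
            if not line.strip():
                continue
            if set(line.strip().upper()) - IUPAC_DNA:
                return lineno
    return 0


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records in file order, wrapping residues at ``width`` columns."""
    path = Path(path)
    with path.open("w") as handle:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                desc = rec.description
                if desc.startswith(rec.id):
                    header = desc
                else:
                    header = f"{rec.id} {desc}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")


def reverse_complement(residues: str) -> str:
    """IUPAC-aware reverse complement (W<->W, R<->Y, N<->N, ...)."""
    _validate_residues(residues)
    return str(Seq(residues.upper()).reverse_complement())


def extract_region(record: SequenceRecord, region: Region) -> SequenceRecord:
    """Extract a 1-based inclusive region; reverse strand returns the
    reverse complement of the forward-strand slice."""
    if region.end > len(record):
        raise IndexError(
            f"region {region.start}..{region.end} exceeds length {len(record)} "
            f"of record {record.id!r}"
        )
    sub = record.residues[region.start - 1 : region.end]
    if region.strand == "reverse":
        sub = reverse_complement(sub)
    return SequenceRecord(
        id=f"{record.id}:{region.start}-{region.end}({region.strand[0]})",
        residues=sub,
        description=record.description,
    )


def read_alignment(path: str | Path) -> list["GappedRecord"]:
    """Read an aligned-sequence file (CLUSTAL or aligned FASTA).

    Gap characters ``-`` are preserved in the returned rows; use
    :meth:`GappedRecord.ungapped` to recover the plain sequences.
    """
    path = Path(path)
    last_exc: Exception | None = None
    for fmt in ("clustal", "fasta"):
        try:
            aln = AlignIO.read(str(path), fmt)
        except Exception as exc:  # try next format
            last_exc = exc
            continue
        return [GappedRecord(rec.id, str(rec.seq), rec.description) for rec in aln]
    raise FastaParseError(f"{path}: not a CLUSTAL or aligned-FASTA file ({last_exc})")


class GappedRecord:
    """A gapped (aligned) sequence row; '-' allowed, IUPAC letters only."""

    __slots__ = ("id", "residues", "description")

    def __init__(self, id: str, residues: str, description: str = "") -> None:
        residues = residues.upper()
        bad = set(residues) - IUPAC_DNA - {"-"}
        if bad:
            raise FastaParseError(f"illegal residue(s) {sorted(bad)} in aligned row {id!r}")
        self.id = id
        self.residues = residues
        self.description = description

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> SequenceRecord:
        return SequenceRecord(id=self.id, residues=self.residues.replace("-", ""))


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV table with a header row."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
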