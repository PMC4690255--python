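"""File I/O: proteome FASTA, family alignments, TSV conventions.

All text outputs use UNIX newlines, UTF-8 and '.' decimals so that runs
are byte-comparable.  FASTA is wrapped at 60 columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, InputError


@dataclass
class Proteome:
    """A species identifier plus its predicted protein records (id -> residues)."""

    species_id: str
    records: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.items())

    @classmethod
    def from_fasta(cls, path: str | Path, species_id: str | None = None) -> "Proteome":
        path = Path(path)
        if not path.exists():
            raise InputError(f"proteome FASTA not found: {path}")
        records: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise FormatError(f"{path}: duplicate protein id {rec.id!r}")
            records[rec.id] = str(rec.seq).upper()
        return cls(species_id or path.stem, records)

    def to_fasta(self, path: str | Path) -> None:
        write_fasta(path, self.records.items())


def write_fasta(path: str | Path, items: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs as 60-column-wrapped FASTA."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_alignment(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA; all rows must have equal length."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"alignment not found: {path}")
    rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise FormatError(f"{path}: empty alignment")
    lengths = {len(seq) for _, seq in rows}
    if len(lengths) != 1:
        raise FormatError(f"{path}: ragged alignment (row lengths {sorted(lengths)})")
    return rows


def write_tsv(path: str | Path, header: list[str], rows: Iterable[Iterable]) -> None:
    """Deterministic TSV writer (UNIX newlines, repr-free float formatting)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_cell(v) for v in row) + "\n")


def _cell(value) -> str:
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)


def read_tsv(path: str | Path) -> tuple[list[str], list[list[str]]]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"TSV not found: {path}")
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        return [], []
    header = lines[0].split("\t")
    return header, [line.split("\t") for line in lines[1:] if line]


def load_proteome_dir(directory: str | Path) -> list[Proteome]:
    """Load every ``*.fasta``/``*.fa`` in a directory, one proteome per file."""
    directory = Path(directory)
    if not directory.is_dir():
        raise InputError(f"proteome directory not found: {directory}")
    paths = sorted(
        p for p in directory.iterdir() if p.suffix in (".fasta", ".fa", ".faa")
    )
    if not paths:
        raise InputError(f"no FASTA files in {directory}")
    return [Proteome.from_fasta(p) for p in paths]
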