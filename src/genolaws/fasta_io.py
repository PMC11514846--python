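"""FASTA reading/writing and sequence normalization.

The reader normalizes every record for composition counting: lowercase
(soft-masked) bases are uppercased, U is mapped to T so RNA genomes are
analyzable, and alignment gap characters ('-', '.') are stripped.  Both
transformations are recorded per record.  Anything left outside the IUPAC
nucleotide alphabet is a format error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from genolaws.composition import IUPAC_ALPHABET

__all__ = ["FastaFormatError", "GenomeRecord", "read_fasta", "write_fasta", "normalize_sequence"]


class FastaFormatError(ValueError):
    """Raised for structurally invalid FASTA input."""


@dataclass(frozen=True)
class GenomeRecord:
    """One FASTA record after normalization.

    ``id`` is the first whitespace-delimited header token; ``description``
    is the remainder (possibly empty).  ``n_u_mapped`` and ``n_gaps_removed``
    record what normalization changed.
    """

    id: str
    sequence: str
    description: str = ""
    n_u_mapped: int = 0
    n_gaps_removed: int = 0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")


def normalize_sequence(raw: str) -> tuple[str, int, int]:
    """Uppercase, map U→T, strip gaps.

    Returns ``(normalized, n_u_mapped, n_gaps_removed)``.  Idempotent:
    normalizing an already-normalized sequence changes nothing.
    """
    seq = raw.upper()
    n_gaps = seq.count("-") + seq.count(".")
    if n_gaps:
        seq = seq.replace("-", "").replace(".", "")
    n_u = seq.count("U")
    if n_u:
        seq = seq.replace("U", "T")
    return seq, n_u, n_gaps


def read_fasta(path) -> list[GenomeRecord]:
    """Parse a FASTA file into normalized :class:`GenomeRecord` objects.

    Raises :class:`FastaFormatError` for an empty file, a file with no
    header line, a record whose sequence is empty after normalization, or
    a character outside the IUPAC nucleotide set (reported with the record
    id and 0-based offset of the first offender).
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    with open(path) as handle:
        try:
            parsed = list(SeqIO.parse(handle, "fasta"))
        except ValueError as exc:
            raise FastaFormatError(f"{path}: {exc}") from exc
        for seqrec in parsed:
            seq, n_u, n_gaps = normalize_sequence(str(seqrec.seq))
            if not seq:
                raise FastaFormatError(
                    f"{path}: record {seqrec.id!r} has an empty sequence after normalization"
                )
            bad = set(seq) - IUPAC_ALPHABET
            if bad:
                offset = min(seq.index(ch) for ch in bad)
                raise FastaFormatError(
                    f"{path}: record {seqrec.id!r} has non-IUPAC character "
                    f"{seq[offset]!r} at offset {offset}"
                )
            description = seqrec.description
            if description.startswith(seqrec.id):
                description = description[len(seqrec.id):].strip()
            records.append(
                GenomeRecord(
                    id=seqrec.id,
                    sequence=seq,
                    description=description,
                    n_u_mapped=n_u,
                    n_gaps_removed=n_gaps,
                )
            )
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path, line_width: int = 70) -> None:
    """Write records as FASTA with sequence lines wrapped at ``line_width``."""
    if line_width < 1:
        raise ValueError("line_width must be positive")
    records = list(records)
    with open(path, "w") as handle:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for start in range(0, len(rec.sequence), line_width):
                handle.write(rec.sequence[start : start + line_width] + "\n")
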