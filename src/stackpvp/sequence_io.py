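"""Protein sequence I/O, validation and dataset-hygiene filtering.

Reads and writes multi-line FASTA (via Biopython), normalizes case,
and applies the benchmark hygiene rules used for phage virion protein
datasets: sequences with ambiguous or non-standard residues (X, U, Z, B)
and sequences shorter than 50 residues are excluded.  Redundancy removal
(CD-HIT style clustering at 40% identity) is an external preprocessing
step and is deliberately not reimplemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by one-letter code.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
STANDARD_AA_SET = frozenset(STANDARD_AA)

#: Default residues treated as non-standard for filtering.
DEFAULT_FORBIDDEN = frozenset("XUZB")

#: Default minimum sequence length retained after filtering.
DEFAULT_MIN_LENGTH = 50

#: Rejection reason codes.
REASON_SHORT = "SHORT"
REASON_NONSTANDARD = "NONSTANDARD"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus its amino-acid sequence.

    The sequence is stored upper-cased exactly as read; validation against
    the 20-letter alphabet happens in :func:`filter_records`, so records
    holding ambiguous residues can still be represented (and rejected with
    a reason) rather than crashing at parse time.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be a non-empty token, got {self.id!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Rejection:
    """One rejected record: id, its length, and the reason code."""

    id: str
    length: int
    reason: str


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read an ordered list of :class:`ProteinRecord` from a FASTA file.

    Sequences are upper-cased and trailing ``*`` stop characters stripped
    (both are common dialect noise).  Duplicate ids, an empty file, or
    sequence data before the first header are errors.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if not stripped:
        raise ValueError(f"{path}: empty FASTA file")
    if not stripped.startswith(">"):
        raise ValueError(f"{path}: sequence data before the first '>' header")

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            logger.info("stripping trailing '*' from record %s", rec.id)
            seq = seq.rstrip("*")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA with fixed line wrapping."""
    bio = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def filter_records(
    records: Sequence[ProteinRecord],
    min_len: int = DEFAULT_MIN_LENGTH,
    forbidden: frozenset[str] | set[str] = DEFAULT_FORBIDDEN,
) -> tuple[list[ProteinRecord], list[Rejection]]:
    """Apply the dataset hygiene filters; nothing is raised for rejects.

    A record is rejected with reason ``SHORT`` when its raw length is below
    ``min_len`` (length is counted on the raw sequence, before considering
    ambiguous residues), or with reason ``NONSTANDARD`` when it contains a
    forbidden residue or any character outside the 20-letter alphabet.
    ``SHORT`` takes precedence when both apply.

    Returns ``(kept, rejections)``; the two partition the input and both
    preserve input order.
    """
    forbidden = frozenset(c.upper() for c in forbidden)
    kept: list[ProteinRecord] = []
    rejected: list[Rejection] = []
    for rec in records:
        seq = rec.sequence.upper()
        if len(seq) < min_len:
            rejected.append(Rejection(rec.id, len(seq), REASON_SHORT))
        elif (set(seq) - STANDARD_AA_SET) or (set(seq) & forbidden):
            rejected.append(Rejection(rec.id, len(seq), REASON_NONSTANDARD))
        else:
            kept.append(ProteinRecord(rec.id, seq) if seq != rec.sequence else rec)
    return kept, rejected


def write_rejection_report(rejections: Iterable[Rejection], path: str | Path) -> None:
    """Write the rejection report as tab-separated text: id, length, reason."""
    with open(path, "w") as fh:
        fh.write("id\tlength\treason\n")
        for r in rejections:
            fh.write(f"{r.id}\t{r.length}\t{r.reason}\n")
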