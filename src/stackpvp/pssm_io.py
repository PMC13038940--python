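"""Parsing, writing and normalizing PSI-BLAST ASCII PSSM profiles.

A position-specific scoring matrix (PSSM) is the L x 20 log-odds profile
produced by iterative PSI-BLAST search: entry (i, j) scores substitution
of position i by the j-th standard amino acid.  PSI-BLAST's
``-out_ascii_pssm`` dialect prints, per position, the position index, the
query residue, 20 integer log-odds columns, 20 weighted-percentage
columns, and two trailing real-valued columns, framed by header and
footer lines.  Only the log-odds block is used by the evolutionary
descriptors, so only it is retained.

Columns are remapped at parse time from the file's order (PSI-BLAST uses
``A R N D C Q E G H I L K M F P S T W Y V``) to a fixed canonical order —
alphabetical by one-letter code — so downstream encoders never depend on
file layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np

from .sequence_io import STANDARD_AA, STANDARD_AA_SET

#: Column order used by PSI-BLAST ASCII output.
PSIBLAST_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Canonical internal column order (alphabetical one-letter codes).
CANONICAL_COLUMN_ORDER = STANDARD_AA

_NORMALIZATION_MODES = ("raw", "sigmoid", "row_standard")


@dataclass(frozen=True)
class PssmProfile:
    """An L x 20 log-odds profile with its residue string.

    ``scores`` rows follow ``residues``; columns follow ``column_order``
    (the canonical alphabetical order unless a caller constructs
    otherwise).  Scores are floats; freshly parsed profiles hold integer
    values, normalized ones real values.
    """

    residues: str
    scores: np.ndarray
    column_order: str = CANONICAL_COLUMN_ORDER

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError(f"scores must be L x 20, got shape {scores.shape}")
        if scores.shape[0] != len(self.residues):
            raise ValueError(
                f"residue count {len(self.residues)} != score rows {scores.shape[0]}"
            )
        if len(self.residues) == 0:
            raise ValueError("empty profile")
        if sorted(self.column_order) != sorted(STANDARD_AA):
            raise ValueError("column_order must be a permutation of the 20 standard letters")
        bad = set(self.residues) - STANDARD_AA_SET
        if bad:
            raise ValueError(f"non-standard residues in profile: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def column(self, aa: str) -> np.ndarray:
        """Score column for amino acid ``aa``."""
        return self.scores[:, self.column_order.index(aa)]


def _data_lines(lines: list[str]) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, line) for candidate matrix rows."""
    for num, line in enumerate(lines, start=1):
        yield num, line


def parse_psiblast_pssm(path: str | Path) -> PssmProfile:
    """Parse a PSI-BLAST ASCII PSSM file into a :class:`PssmProfile`.

    Only the first 20 numeric columns (log-odds) are kept; the
    weighted-percentage block and the two trailing reals are validated for
    presence but discarded, and footer lines (K/lambda statistics) are
    ignored.  Raises ``ValueError`` naming the offending line for
    malformed rows.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    # locate the column-label line: 40 single-letter tokens
    header_idx = None
    file_order = None
    for i, line in enumerate(lines):
        toks = line.split()
        if len(toks) == 40 and all(len(t) == 1 and t in STANDARD_AA_SET for t in toks):
            header_idx = i
            file_order = "".join(toks[:20])
            if toks[:20] != toks[20:]:
                raise ValueError(f"{path}: the two 20-column header blocks disagree")
            break
    if header_idx is None:
        raise ValueError(f"{path}: no 40-letter column-label line found")
    if sorted(file_order) != sorted(STANDARD_AA):
        raise ValueError(f"{path}: header columns are not the 20 standard letters")

    residues: list[str] = []
    rows: list[list[int]] = []
    expected_pos = 1
    in_matrix = False
    for num, raw in _data_lines(lines[header_idx + 1 :]):
        lineno = header_idx + 1 + num  # 1-based in file
        toks = raw.split()
        if not toks:
            if in_matrix:
                break  # blank line ends the matrix; footer follows
            continue
        if not toks[0].isdigit():
            if in_matrix:
                break
            continue
        in_matrix = True
        if len(toks) != 44:
            raise ValueError(
                f"{path}:{lineno}: expected 44 fields "
                f"(index, residue, 42 numeric), got {len(toks)}"
            )
        pos, residue, payload = int(toks[0]), toks[1], toks[2:]
        if pos != expected_pos:
            raise ValueError(f"{path}:{lineno}: position index {pos}, expected {expected_pos}")
        if residue not in STANDARD_AA_SET:
            raise ValueError(f"{path}:{lineno}: non-standard residue {residue!r}")
        try:
            log_odds = [int(t) for t in payload[:20]]
            [int(t) for t in payload[20:40]]
            [float(t) for t in payload[40:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric matrix field ({exc})") from None
        residues.append(residue)
        rows.append(log_odds)
        expected_pos += 1

    if not rows:
        raise ValueError(f"{path}: no matrix rows found")

    scores = np.array(rows, dtype=float)
    # remap file column order -> canonical alphabetical order
    perm = [file_order.index(aa) for aa in CANONICAL_COLUMN_ORDER]
    return PssmProfile(residues="".join(residues), scores=scores[:, perm])


def write_pssm(profile: PssmProfile, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect.

    Percentage columns are written as zeros and the two trailing reals as
    ``0.00``; ``parse_psiblast_pssm`` round-trips the result bit-exactly.
    """
    cols = [profile.column_order.index(aa) for aa in PSIBLAST_COLUMN_ORDER]
    out = profile.scores[:, cols]
    if not np.allclose(out, np.round(out)):
        raise ValueError("write_pssm requires integer-valued scores (raw log-odds)")
    letters = "  ".join(PSIBLAST_COLUMN_ORDER)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed, weighted observed "
                 "percentages rounded down, information per position, and relative "
                 "weight of gapless real matches to pseudocounts\n")
        fh.write(" " * 11 + letters + "   " + letters + "\n")
        for i, residue in enumerate(profile.residues):
            nums = "".join(f"{int(round(v)):4d}" for v in out[i])
            pcts = "".join(f"{0:4d}" for _ in range(20))
            fh.write(f"{i + 1:5d} {residue}  {nums} {pcts}  0.00 0.00\n")
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1347     0.3176\n")


def normalize_scores(profile: PssmProfile, mode: str = "raw") -> PssmProfile:
    """Return a profile with normalized scores.

    Modes: ``raw`` (identity), ``sigmoid`` (elementwise 1/(1+e^-p)),
    ``row_standard`` (each row centered and scaled to unit variance across
    its 20 entries; zero-variance rows map to all-zeros).
    """
    if mode not in _NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}; choose from {_NORMALIZATION_MODES}")
    if mode == "raw":
        return profile
    if mode == "sigmoid":
        return replace(profile, scores=1.0 / (1.0 + np.exp(-profile.scores)))
    mean = profile.scores.mean(axis=1, keepdims=True)
    std = profile.scores.std(axis=1, keepdims=True)  # population std over the 20 entries
    centered = profile.scores - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        standardized = np.where(std > 0, centered / np.where(std > 0, std, 1.0), 0.0)
    return replace(profile, scores=standardized)


def read_pssm_directory(directory: str | Path, ids: list[str]) -> dict[str, PssmProfile]:
    """Load ``<id>.pssm`` files for every id; missing files are an error."""
    directory = Path(directory)
    missing = [i for i in ids if not (directory / f"{i}.pssm").exists()]
    if missing:
        raise FileNotFoundError(
            f"missing PSSM files in {directory} for ids: {', '.join(missing)}"
        )
    return {i: parse_psiblast_pssm(directory / f"{i}.pssm") for i in ids}
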