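"""Classical sequence descriptors: AAC, DPC, GAAC, GDPC, CTDC, CTDT, CTDD.

Seven composition/physicochemistry encodings computed directly from the
amino-acid string, totalling 723 features
(20 + 400 + 5 + 25 + 39 + 39 + 195).  They serve as the comparison
feature family for the PSSM-derived evolutionary descriptors.

* AAC / DPC: frequencies of residues and of overlapping ordered
  dipeptides.
* GAAC / GDPC: the same after mapping residues onto five physicochemical
  groups (aliphatic, aromatic, positively charged, negatively charged,
  uncharged).
* CTD: for each of 13 properties splitting the alphabet into 3 groups —
  composition (group fractions), transition (adjacent-pair group-change
  frequencies), distribution (positions, as % of sequence length, of the
  first / 25% / 50% / 75% / last occurrence of each group).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._ctd_constants import CTD_GROUPS, CTD_PROPERTIES, GAAC_GROUPS
from .sequence_io import STANDARD_AA, ProteinRecord

SEQUENCE_DIM = 723
_BLOCK_DIMS = {
    "AAC": 20, "DPC": 400, "GAAC": 5, "GDPC": 25,
    "CTDC": 39, "CTDT": 39, "CTDD": 195, "ALL": 723,
}

_GROUP_TAGS = tuple(GAAC_GROUPS)


@dataclass(frozen=True)
class SequenceVector:
    """A named descriptor vector from one block (or the 723-dim concatenation)."""

    values: np.ndarray
    names: tuple[str, ...]
    block: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.block not in _BLOCK_DIMS:
            raise ValueError(f"unknown block {self.block!r}")
        expected = _BLOCK_DIMS[self.block]
        if values.shape != (expected,) or len(self.names) != expected:
            raise ValueError(
                f"block {self.block} must have {expected} values/names, "
                f"got {values.shape} / {len(self.names)}"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")


def _check(record: ProteinRecord, min_len: int = 1, what: str = "descriptor") -> str:
    seq = record.sequence
    if len(seq) < min_len:
        raise ValueError(f"{what} requires length >= {min_len}, got {len(seq)} for {record.id}")
    bad = set(seq) - set(STANDARD_AA)
    if bad:
        raise ValueError(f"record {record.id} holds non-standard residues {sorted(bad)}")
    return seq


AAC_NAMES = tuple(f"AAC_{aa}" for aa in STANDARD_AA)
DPC_NAMES = tuple(f"DPC_{a}{b}" for a in STANDARD_AA for b in STANDARD_AA)
GAAC_NAMES = tuple(f"GAAC_{g}" for g in _GROUP_TAGS)
GDPC_NAMES = tuple(f"GDPC_{a}_{b}" for a in _GROUP_TAGS for b in _GROUP_TAGS)
CTDC_NAMES = tuple(f"CTDC_{p}_g{g}" for p in CTD_PROPERTIES for g in (1, 2, 3))
CTDT_NAMES = tuple(f"CTDT_{p}_{t}" for p in CTD_PROPERTIES for t in ("12", "13", "23"))
CTDD_NAMES = tuple(
    f"CTDD_{p}_g{g}_{q}"
    for p in CTD_PROPERTIES
    for g in (1, 2, 3)
    for q in ("first", "p25", "p50", "p75", "last")
)


def aac(record: ProteinRecord) -> SequenceVector:
    """Residue frequencies (sum to 1)."""
    seq = _check(record, 1, "AAC")
    counts = Counter(seq)
    vals = np.array([counts.get(aa, 0) for aa in STANDARD_AA], dtype=float) / len(seq)
    return SequenceVector(vals, AAC_NAMES, "AAC")


def dpc(record: ProteinRecord) -> SequenceVector:
    """Ordered overlapping-dipeptide frequencies (sum to 1)."""
    seq = _check(record, 2, "DPC")
    counts = Counter(zip(seq, seq[1:]))
    vals = np.array(
        [counts.get((a, b), 0) for a in STANDARD_AA for b in STANDARD_AA], dtype=float
    ) / (len(seq) - 1)
    return SequenceVector(vals, DPC_NAMES, "DPC")


_AA_TO_GROUP = {aa: tag for tag, members in GAAC_GROUPS.items() for aa in members}


def gaac(record: ProteinRecord) -> SequenceVector:
    """Grouped amino-acid composition over the five physicochemical classes."""
    seq = _check(record, 1, "GAAC")
    counts = Counter(_AA_TO_GROUP[c] for c in seq)
    vals = np.array([counts.get(g, 0) for g in _GROUP_TAGS], dtype=float) / len(seq)
    return SequenceVector(vals, GAAC_NAMES, "GAAC")


def gdpc(record: ProteinRecord) -> SequenceVector:
    """Grouped dipeptide composition over the five physicochemical classes."""
    seq = _check(record, 2, "GDPC")
    pairs = Counter(
        (_AA_TO_GROUP[a], _AA_TO_GROUP[b]) for a, b in zip(seq, seq[1:])
    )
    vals = np.array(
        [pairs.get((a, b), 0) for a in _GROUP_TAGS for b in _GROUP_TAGS], dtype=float
    ) / (len(seq) - 1)
    return SequenceVector(vals, GDPC_NAMES, "GDPC")


def _group_indices(seq: str, groups: tuple[str, str, str]) -> np.ndarray:
    """Per-position group index (1, 2 or 3) for one property."""
    lookup = {}
    for g, members in enumerate(groups, start=1):
        for aa in members:
            lookup[aa] = g
    return np.fromiter((lookup[c] for c in seq), dtype=int, count=len(seq))


def ctdc(record: ProteinRecord) -> SequenceVector:
    """Composition: per property, the fraction of residues in each group."""
    seq = _check(record, 1, "CTDC")
    vals = []
    for prop in CTD_PROPERTIES:
        g = _group_indices(seq, CTD_GROUPS[prop])
        for k in (1, 2, 3):
            vals.append(np.count_nonzero(g == k) / len(seq))
    return SequenceVector(np.array(vals), CTDC_NAMES, "CTDC")


def ctdt(record: ProteinRecord) -> SequenceVector:
    """Transition: per property, frequencies of 1<->2, 1<->3, 2<->3 adjacent changes."""
    seq = _check(record, 2, "CTDT")
    vals = []
    for prop in CTD_PROPERTIES:
        g = _group_indices(seq, CTD_GROUPS[prop])
        a, b = g[:-1], g[1:]
        for x, y in ((1, 2), (1, 3), (2, 3)):
            n = np.count_nonzero(((a == x) & (b == y)) | ((a == y) & (b == x)))
            vals.append(n / (len(seq) - 1))
    return SequenceVector(np.array(vals), CTDT_NAMES, "CTDT")


def ctdd(record: ProteinRecord) -> SequenceVector:
    """Distribution: per property and group, the sequence positions (as a
    percentage of length, 1-based) of the first, 25%, 50%, 75% and last
    occurrence; all five are 0 for groups absent from the sequence.
    Fractional occurrence counts round up (ceiling)."""
    seq = _check(record, 1, "CTDD")
    L = len(seq)
    vals = []
    for prop in CTD_PROPERTIES:
        g = _group_indices(seq, CTD_GROUPS[prop])
        for k in (1, 2, 3):
            pos = np.flatnonzero(g == k) + 1  # 1-based positions
            if pos.size == 0:
                vals.extend([0.0] * 5)
                continue
            n = pos.size
            for frac in (0.0, 0.25, 0.50, 0.75, 1.0):
                idx = max(1, math.ceil(frac * n))
                vals.append(pos[idx - 1] / L * 100.0)
    return SequenceVector(np.array(vals), CTDD_NAMES, "CTDD")


def ctd(record: ProteinRecord) -> tuple[SequenceVector, SequenceVector, SequenceVector]:
    """The three CTD blocks (CTDC, CTDT, CTDD) together."""
    return ctdc(record), ctdt(record), ctdd(record)


def encode_sequence(record: ProteinRecord) -> SequenceVector:
    """The 723-dim concatenation AAC | DPC | GAAC | GDPC | CTDC | CTDT | CTDD."""
    parts = [aac(record), dpc(record), gaac(record), gdpc(record),
             ctdc(record), ctdt(record), ctdd(record)]
    values = np.concatenate([p.values for p in parts])
    names = tuple(n for p in parts for n in p.names)
    return SequenceVector(values, names, "ALL")


SEQUENCE_NAMES = (
    AAC_NAMES + DPC_NAMES + GAAC_NAMES + GDPC_NAMES + CTDC_NAMES + CTDT_NAMES + CTDD_NAMES
)
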