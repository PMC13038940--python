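"""PSSM-derived evolutionary descriptors: AAC-PSSM, DPC-PSSM, PSSM-COM, Pse-PSSM.

Four complementary encodings of the L x 20 log-odds profile p(k, j):

* AAC-PSSM (20): per-column means, x_j = (1/L) * sum_k p(k, j) — the
  average propensity of the protein to mutate toward amino acid j.
* DPC-PSSM (400): adjacent-row column-pair products,
  y(i, j) = (1/(L-1)) * sum_{k<L} p(k, i) * p(k+1, j) — local
  residue-pair dependency.
* PSSM-COM (400): the 20 x 20 matrix whose i-th row is the sum of PSSM
  rows at positions whose *sequence* residue is the i-th standard amino
  acid (optionally divided by L) — position-aware composition.
* Pse-PSSM (40): 20 means of the row-standardized profile plus 20
  lag-xi squared-difference terms,
  (1/(L-xi)) * sum_k (p~(k, j) - p~(k+xi, j))^2 — sequence-order
  correlation, in the spirit of pseudo amino-acid composition.

Concatenated in the order AAC-PSSM | DPC-PSSM | PSSM-COM | Pse-PSSM they
give the 860-dimensional evolutionary feature vector.

Normalization defaults follow the descriptors' original definitions: raw
log-odds for AAC-PSSM, DPC-PSSM and PSSM-COM; row standardization for
Pse-PSSM (applied internally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pssm_io import CANONICAL_COLUMN_ORDER, PssmProfile, normalize_scores
from .sequence_io import STANDARD_AA

EVOLUTIONARY_DIM = 860
_BLOCKS = ("AAC-PSSM", "DPC-PSSM", "PSSM-COM", "Pse-PSSM")
_BLOCK_DIMS = {"AAC-PSSM": 20, "DPC-PSSM": 400, "PSSM-COM": 400, "Pse-PSSM": 40, "ALL": 860}


@dataclass(frozen=True)
class EvolutionaryVector:
    """A named descriptor vector from one block (or the 860-dim concatenation)."""

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


def _canonical(profile: PssmProfile) -> np.ndarray:
    """Scores with columns in canonical alphabetical order."""
    if profile.column_order == CANONICAL_COLUMN_ORDER:
        return profile.scores
    perm = [profile.column_order.index(aa) for aa in CANONICAL_COLUMN_ORDER]
    return profile.scores[:, perm]


AAC_PSSM_NAMES = tuple(f"AACPSSM_{aa}" for aa in STANDARD_AA)
DPC_PSSM_NAMES = tuple(f"DPCPSSM_{a}_{b}" for a in STANDARD_AA for b in STANDARD_AA)
PSSM_COM_NAMES = tuple(f"PSSMCOM_{a}_{b}" for a in STANDARD_AA for b in STANDARD_AA)
PSE_PSSM_NAMES = tuple(
    [f"PSEPSSM_mean_{aa}" for aa in STANDARD_AA] + [f"PSEPSSM_lag_{aa}" for aa in STANDARD_AA]
)


def aac_pssm(profile: PssmProfile) -> EvolutionaryVector:
    """Column means of the profile: the 20 AAC-PSSM features."""
    p = _canonical(profile)
    return EvolutionaryVector(p.mean(axis=0), AAC_PSSM_NAMES, "AAC-PSSM")


def dpc_pssm(profile: PssmProfile) -> EvolutionaryVector:
    """Adjacent-row column-pair products: the 400 DPC-PSSM features.

    y(i, j) averages p(k, i) * p(k+1, j) over the L-1 successive row
    pairs; flattened row-major over (i, j).
    """
    p = _canonical(profile)
    if p.shape[0] < 2:
        raise ValueError("DPC-PSSM requires L >= 2 (no successive-row pair exists)")
    y = p[:-1].T @ p[1:] / (p.shape[0] - 1)
    return EvolutionaryVector(y.ravel(), DPC_PSSM_NAMES, "DPC-PSSM")


def pssm_composition(profile: PssmProfile, length_normalize: bool = True) -> EvolutionaryVector:
    """Residue-grouped row sums: the 400 PSSM-COM features.

    Row i of the 20 x 20 output is the (optionally length-normalized) sum
    of the PSSM rows at sequence positions holding the i-th standard
    amino acid; amino acids absent from the sequence give all-zero rows.
    """
    p = _canonical(profile)
    out = np.zeros((20, 20))
    for i, aa in enumerate(STANDARD_AA):
        mask = np.fromiter((r == aa for r in profile.residues), dtype=bool, count=p.shape[0])
        if mask.any():
            out[i] = p[mask].sum(axis=0)
    if length_normalize:
        out /= p.shape[0]
    return EvolutionaryVector(out.ravel(), PSSM_COM_NAMES, "PSSM-COM")


def pse_pssm(profile: PssmProfile, xi: int = 1) -> EvolutionaryVector:
    """Pseudo-PSSM: 20 profile means + 20 lag-xi squared-difference terms.

    The profile is row-standardized first (each row rescaled to zero mean
    and unit variance over its 20 entries), then component j of the first
    block is the mean of column j and component 20+j is
    (1/(L-xi)) * sum_{k=1..L-xi} (p~(k,j) - p~(k+xi,j))^2.
    """
    if xi < 1:
        raise ValueError(f"xi must be a positive integer, got {xi}")
    if profile.length <= xi:
        raise ValueError(f"Pse-PSSM requires L > xi (L={profile.length}, xi={xi})")
    p = _canonical(normalize_scores(profile, "row_standard"))
    means = p.mean(axis=0)
    diffs = ((p[:-xi] - p[xi:]) ** 2).mean(axis=0)
    return EvolutionaryVector(np.concatenate([means, diffs]), PSE_PSSM_NAMES, "Pse-PSSM")


def encode_evolutionary(
    profile: PssmProfile, xi: int = 1, length_normalize: bool = True
) -> EvolutionaryVector:
    """The 860-dim concatenation AAC-PSSM | DPC-PSSM | PSSM-COM | Pse-PSSM."""
    parts = [
        aac_pssm(profile),
        dpc_pssm(profile),
        pssm_composition(profile, length_normalize=length_normalize),
        pse_pssm(profile, xi=xi),
    ]
    values = np.concatenate([p.values for p in parts])
    names = tuple(n for p in parts for n in p.names)
    return EvolutionaryVector(values, names, "ALL")


EVOLUTIONARY_NAMES = AAC_PSSM_NAMES + DPC_PSSM_NAMES + PSSM_COM_NAMES + PSE_PSSM_NAMES
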