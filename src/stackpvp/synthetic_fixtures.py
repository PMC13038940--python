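"""Synthetic sequences, PSSM profiles and labeled datasets for testing.

Real phage-protein benchmarks need PSI-BLAST profiles against UniRef50,
which cannot be regenerated at desk scale, so every pipeline stage is
exercised instead on synthetic data with a controllable class signal.

Profiles emulate random-coil PSI-BLAST output: integer log-odds drawn
from a rounded, clipped normal over the realistic [-10, 10] range, so
parser edge cases (negative values, double-digit magnitudes, column
alignment) are exercised.  The class signal is a +delta mean shift
applied to a chosen subset of profile columns for positive-class
samples — planted in evolutionary space, where the classifier is meant
to look.  A sequence-composition signal mode exists to exercise the
classical-descriptor path instead: positives over-sample a chosen
residue subset.

These fixtures deliberately do not emulate homology structure, domain
architecture or realistic phylogenetic correlation between samples;
passing tests show the machinery recovers a planted signal, not that
real phage proteins are this separable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pssm_io import PssmProfile, write_pssm
from .sequence_io import STANDARD_AA, ProteinRecord, write_fasta

#: log-odds support of real PSI-BLAST ASCII output.
SCORE_MIN, SCORE_MAX = -10, 10


@dataclass(frozen=True)
class FixtureConfig:
    """Generator settings: sizes, lengths, class-signal placement and strength."""

    n_pos: int = 100
    n_neg: int = 100
    length_range: tuple[int, int] = (60, 120)
    effect_size: float = 0.0
    signal_columns: tuple[int, ...] = (0, 1, 2, 3)
    seed: int = 0
    score_scale: float = 2.0      # sd of the base log-odds distribution
    signal_mode: str = "pssm"     # "pssm" | "sequence"
    signal_residues: tuple[str, ...] = ("A", "C", "D", "E")

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.signal_mode not in ("pssm", "sequence"):
            raise ValueError(f"unknown signal_mode {self.signal_mode!r}")
        if any(not 0 <= c < 20 for c in self.signal_columns):
            raise ValueError("signal_columns must index the 20 profile columns")


def _residue_weights(cfg: FixtureConfig, class_label: int) -> np.ndarray:
    w = np.ones(20)
    if cfg.signal_mode == "sequence" and class_label == 1 and cfg.effect_size > 0:
        for aa in cfg.signal_residues:
            w[STANDARD_AA.index(aa)] += cfg.effect_size
    return w / w.sum()


def synth_sequence(length: int, class_label: int, cfg: FixtureConfig, rng: np.random.Generator) -> str:
    """Random sequence over the 20-letter alphabet; composition shifted for
    positives in ``sequence`` signal mode."""
    if length < 2:
        raise ValueError(f"length must be >= 2, got {length}")
    w = _residue_weights(cfg, class_label)
    return "".join(rng.choice(list(STANDARD_AA), size=length, p=w))


def synth_pssm(
    length: int,
    class_label: int,
    cfg: FixtureConfig,
    rng: np.random.Generator | None = None,
    residues: str | None = None,
) -> PssmProfile:
    """A synthetic L x 20 integer log-odds profile.

    Scores are round(N(mu, score_scale)) clipped to [-10, 10]; mu is
    ``effect_size`` on ``signal_columns`` for positive-class profiles
    (``pssm`` signal mode) and 0 elsewhere.  Deterministic given the rng
    state (a fresh one is derived from ``cfg.seed`` when omitted).
    """
    if length < 2:
        raise ValueError(f"length must be >= 2, got {length}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    mu = np.zeros(20)
    if cfg.signal_mode == "pssm" and class_label == 1:
        mu[list(cfg.signal_columns)] = cfg.effect_size
    raw = rng.normal(loc=mu, scale=cfg.score_scale, size=(length, 20))
    scores = np.clip(np.round(raw), SCORE_MIN, SCORE_MAX)
    if residues is None:
        residues = synth_sequence(length, class_label, cfg, rng)
    return PssmProfile(residues=residues, scores=scores)


def make_dataset(
    cfg: FixtureConfig,
) -> tuple[list[ProteinRecord], dict[str, PssmProfile], dict[str, int]]:
    """In-memory paired records/profiles/labels (positives first)."""
    rng = np.random.default_rng(cfg.seed)
    records: list[ProteinRecord] = []
    profiles: dict[str, PssmProfile] = {}
    labels: dict[str, int] = {}
    for class_label, count, prefix in ((1, cfg.n_pos, "pvp"), (0, cfg.n_neg, "neg")):
        for i in range(count):
            length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
            seq = synth_sequence(length, class_label, cfg, rng)
            rec = ProteinRecord(id=f"{prefix}{i:04d}", sequence=seq)
            records.append(rec)
            profiles[rec.id] = synth_pssm(length, class_label, cfg, rng, residues=seq)
            labels[rec.id] = class_label
    return records, profiles, labels


def synth_dataset(cfg: FixtureConfig, out_dir: str | Path) -> dict:
    """Write a complete on-disk dataset: FASTA, per-id .pssm files, labels,
    and a manifest recording the generator parameters and seed."""
    out_dir = Path(out_dir)
    pssm_dir = out_dir / "pssm"
    pssm_dir.mkdir(parents=True, exist_ok=True)
    records, profiles, labels = make_dataset(cfg)
    write_fasta(records, out_dir / "sequences.fasta")
    for rec in records:
        write_pssm(profiles[rec.id], pssm_dir / f"{rec.id}.pssm")
    with open(out_dir / "labels.tsv", "w") as fh:
        fh.write("id\tlabel\n")
        for rec in records:
            fh.write(f"{rec.id}\t{labels[rec.id]}\n")
    manifest = {
        "n_pos": cfg.n_pos, "n_neg": cfg.n_neg,
        "length_range": list(cfg.length_range),
        "effect_size": cfg.effect_size,
        "signal_columns": list(cfg.signal_columns),
        "signal_mode": cfg.signal_mode,
        "seed": cfg.seed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return {
        "fasta": out_dir / "sequences.fasta",
        "pssm_dir": pssm_dir,
        "labels": out_dir / "labels.tsv",
        "manifest": out_dir / "manifest.json",
    }


def read_labels(path: str | Path) -> dict[str, int]:
    labels = {}
    for line in Path(path).read_text().splitlines()[1:]:
        k, v = line.split("\t")
        labels[k] = int(v)
    return labels
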