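"""Feature selection: ANOVA F-score ranking, variance thresholding, RFECV.

Selections are fit on training data only and captured as a
:class:`SelectionResult` holding the ordered kept feature names, so the
same columns (in the same order) can be re-extracted from any matrix
sharing the training feature names — selection is never recomputed on
held-out data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.feature_selection import RFECV
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC


@dataclass(frozen=True)
class FeatureMatrix:
    """n samples x d named features with binary labels (PVP = 1)."""

    ids: tuple[str, ...]
    X: np.ndarray
    names: tuple[str, ...]
    y: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "names", tuple(self.names))
        n, d = X.shape
        if len(self.ids) != n or y.shape != (n,):
            raise ValueError("ids / X / y sample counts disagree")
        if len(self.names) != d:
            raise ValueError("names / X feature counts disagree")
        if len(set(self.names)) != d:
            raise ValueError("feature names must be unique")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, index=list(self.ids), columns=list(self.names))
        df.insert(0, "label", self.y)
        df.index.name = "id"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        if "label" not in df.columns:
            raise ValueError("frame must carry a 'label' column")
        names = [c for c in df.columns if c != "label"]
        return cls(
            ids=tuple(str(i) for i in df.index),
            X=df[names].to_numpy(dtype=float),
            names=tuple(names),
            y=df["label"].to_numpy(dtype=int),
        )


@dataclass(frozen=True)
class SelectionResult:
    """A fitted selection: method tag, ordered kept names, scores, parameters."""

    method: str  # "F", "Var" or "RFECV"
    kept_names: tuple[str, ...]
    scores: dict[str, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        """Serialize as JSON-headed delimited text, replayable at predict time."""
        with open(path, "w") as fh:
            fh.write("#" + json.dumps({"method": self.method, "params": self.params}) + "\n")
            fh.write("name\tscore\n")
            for name in self.kept_names:
                fh.write(f"{name}\t{self.scores.get(name, float('nan'))!r}\n")

    @classmethod
    def load(cls, path: str | Path) -> "SelectionResult":
        lines = Path(path).read_text().splitlines()
        meta = json.loads(lines[0].lstrip("#"))
        kept, scores = [], {}
        for line in lines[2:]:
            name, score = line.split("\t")
            kept.append(name)
            scores[name] = float(score)
        return cls(meta["method"], tuple(kept), scores, meta["params"])


def f_score_rank(fm: FeatureMatrix) -> np.ndarray:
    """Two-group one-way ANOVA F statistic per feature.

    F_j = between-group mean square / within-group mean square.  A feature
    constant within each class but differing between classes gets +inf (it
    separates perfectly and ranks first); a feature with zero variance
    everywhere gets 0.
    """
    y = fm.y
    if len(np.unique(y)) < 2:
        raise ValueError("F-score needs both classes present")
    if fm.n < 3:
        raise ValueError("F-score needs n >= 3")
    X = fm.X
    grand = X.mean(axis=0)
    between = np.zeros(fm.d)
    within = np.zeros(fm.d)
    for c in (0, 1):
        Xc = X[y == c]
        between += Xc.shape[0] * (Xc.mean(axis=0) - grand) ** 2
        within += ((Xc - Xc.mean(axis=0)) ** 2).sum(axis=0)
    msb = between / (2 - 1)
    msw = within / (fm.n - 2)
    F = np.empty(fm.d)
    zero_w = msw == 0
    F[~zero_w] = msb[~zero_w] / msw[~zero_w]
    F[zero_w & (msb > 0)] = np.inf
    F[zero_w & (msb == 0)] = 0.0
    return F


def f_select(fm: FeatureMatrix, k: int) -> SelectionResult:
    """Keep the top-k features by F statistic; ties broken by original order."""
    if not 1 <= k <= fm.d:
        raise ValueError(f"k must be in [1, {fm.d}], got {k}")
    F = f_score_rank(fm)
    order = np.lexsort((np.arange(fm.d), -F))  # F desc, then index asc
    kept_idx = order[:k]
    kept = tuple(fm.names[i] for i in kept_idx)
    return SelectionResult(
        "F", kept, {n: float(F[i]) for i, n in zip(kept_idx, kept)}, {"k": k}
    )


def variance_select(fm: FeatureMatrix, threshold: float) -> SelectionResult:
    """Keep features with population variance >= threshold, original order."""
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    if fm.n < 2:
        raise ValueError("variance selection needs n >= 2")
    var = fm.X.var(axis=0)  # population variance (ddof=0)
    kept_idx = np.flatnonzero(var >= threshold)
    kept = tuple(fm.names[i] for i in kept_idx)
    return SelectionResult(
        "Var", kept, {n: float(var[i]) for i, n in zip(kept_idx, kept)},
        {"threshold": float(threshold)},
    )


#: RFECV internal estimators, keyed by tag.
RFECV_ESTIMATORS = {
    "linear-svm": lambda seed: LinearSVC(C=1.0, dual="auto", max_iter=5000, random_state=seed),
    "logistic": lambda seed: LogisticRegression(max_iter=2000, random_state=seed),
    "random-forest": lambda seed: RandomForestClassifier(n_estimators=100, random_state=seed),
    "extra-trees": lambda seed: ExtraTreesClassifier(n_estimators=100, random_state=seed),
}


def rfecv_select(
    fm: FeatureMatrix,
    estimator_tag: str = "linear-svm",
    cv_folds: int = 10,
    step: int = 1,
    seed: int = 0,
) -> SelectionResult:
    """Recursive feature elimination with cross-validated subset sizing.

    Removes ``step`` lowest-importance features per round; the kept size
    maximizes mean accuracy over stratified folds (ties resolve to the
    smallest count).  Deterministic given the seed.
    """
    if estimator_tag not in RFECV_ESTIMATORS:
        raise ValueError(
            f"unknown estimator tag {estimator_tag!r}; choose from {sorted(RFECV_ESTIMATORS)}"
        )
    if fm.n < cv_folds:
        raise ValueError(f"n={fm.n} < cv_folds={cv_folds}")
    if fm.d == 1:  # nothing to eliminate
        return SelectionResult(
            "RFECV", fm.names, {fm.names[0]: 1.0},
            {"estimator": estimator_tag, "cv_folds": cv_folds, "step": step, "seed": seed},
        )
    est = RFECV_ESTIMATORS[estimator_tag](seed)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    selector = RFECV(est, step=step, cv=cv, scoring="accuracy", min_features_to_select=1)
    selector.fit(fm.X, fm.y)
    kept_idx = np.flatnonzero(selector.support_)
    kept = tuple(fm.names[i] for i in kept_idx)
    ranks = {n: float(selector.ranking_[i]) for i, n in zip(np.arange(fm.d), fm.names)}
    return SelectionResult(
        "RFECV",
        kept,
        {n: ranks[n] for n in kept},
        {"estimator": estimator_tag, "cv_folds": cv_folds, "step": step, "seed": seed},
    )


def apply_selection(fm: FeatureMatrix, sel: SelectionResult) -> FeatureMatrix:
    """Subset and reorder columns to ``sel.kept_names``; ids/labels unchanged."""
    index = {n: i for i, n in enumerate(fm.names)}
    missing = [n for n in sel.kept_names if n not in index]
    if missing:
        raise KeyError(f"features absent from matrix: {missing}")
    cols = [index[n] for n in sel.kept_names]
    return FeatureMatrix(fm.ids, fm.X[:, cols], sel.kept_names, fm.y)
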