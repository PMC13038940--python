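"""Two-layer stacked ensemble with out-of-fold meta-features.

Layer 1: for each reduced feature set (one per selector: F, Var, RFECV),
twelve base classifiers are trained under a shared stratified 10-fold
plan; each training row's meta-feature is the positive-class probability
predicted by the fold model that never saw that row (out-of-fold, so the
meta-layer cannot leak), and a refit on all rows is stored for
inference.

Layer 2: the out-of-fold probability blocks from the chosen selector
subset are concatenated (width 12 x |blocks|) and fed to a
meta-classifier (LR, RF or SVM).  The experiment grid spans all 7
non-empty selector subsets x 3 meta tags = 21 stacked configurations,
on top of 12 x 3 = 36 base models.  The reference configuration is the
F + RFECV block pair with a random-forest meta-classifier.

Meta-features are probabilities, not hard labels: they preserve the base
models' confidence, the standard stacking choice.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np

from .feature_selection import FeatureMatrix, SelectionResult, apply_selection

SELECTOR_ORDER = ("F", "Var", "RFECV")

#: The twelve base-learner slots, in canonical order.
DEFAULT_ALGORITHMS = (
    "DT", "RF", "EF", "GBDT", "XGBoost", "LightGBM",
    "AdaBoost", "CatBoost", "SVM", "ANN", "KNN", "MLP",
)

META_TAGS = ("LR", "RF", "SVM")

#: Final-model reference configuration: F + RFECV blocks, RF meta.
FINAL_BLOCKS = ("F", "RFECV")
FINAL_META = "RF"


def _build_estimator(tag: str, seed: int, params: Mapping | None = None):
    """Instantiate the estimator behind a base-learner tag.

    Hyperparameters default to each library's documented defaults with
    seeds pinned and single-threaded execution for reproducibility; any
    can be overridden through ``params``.
    """
    params = dict(params or {})
    if tag == "DT":
        from sklearn.tree import DecisionTreeClassifier
        return DecisionTreeClassifier(random_state=seed, **params)
    if tag == "RF":
        from sklearn.ensemble import RandomForestClassifier
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if tag == "EF":
        from sklearn.ensemble import ExtraTreesClassifier
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **params)
    if tag == "GBDT":
        from sklearn.ensemble import GradientBoostingClassifier
        return GradientBoostingClassifier(random_state=seed, **params)
    if tag == "XGBoost":
        try:
            from xgboost import XGBClassifier
        except ImportError as exc:
            raise ImportError(f"base algorithm XGBoost needs the xgboost package: {exc}")
        params.setdefault("eval_metric", "logloss")
        return XGBClassifier(random_state=seed, n_jobs=1, **params)
    if tag == "LightGBM":
        try:
            from lightgbm import LGBMClassifier
        except ImportError as exc:
            raise ImportError(f"base algorithm LightGBM needs the lightgbm package: {exc}")
        params.setdefault("verbose", -1)
        params.setdefault("deterministic", True)
        params.setdefault("force_col_wise", True)
        return LGBMClassifier(random_state=seed, n_jobs=1, **params)
    if tag == "AdaBoost":
        from sklearn.ensemble import AdaBoostClassifier
        return AdaBoostClassifier(random_state=seed, **params)
    if tag == "CatBoost":
        try:
            from catboost import CatBoostClassifier
        except ImportError as exc:
            raise ImportError(
                "base algorithm CatBoost needs the catboost package, which is not "
                f"installed: {exc}. Use BaseLayerSpec(algorithms=available_algorithms()) "
                "for the documented fallback without it."
            )
        params.setdefault("verbose", False)
        return CatBoostClassifier(random_seed=seed, **params)
    if tag == "SVM":
        from sklearn.svm import SVC
        params.setdefault("probability", True)
        return SVC(random_state=seed, **params)
    if tag == "ANN":
        from sklearn.neural_network import MLPClassifier
        params.setdefault("hidden_layer_sizes", (32,))
        params.setdefault("max_iter", 500)
        return MLPClassifier(random_state=seed, **params)
    if tag == "KNN":
        from sklearn.neighbors import KNeighborsClassifier
        return KNeighborsClassifier(n_jobs=1, **params)
    if tag == "MLP":
        from sklearn.neural_network import MLPClassifier
        params.setdefault("hidden_layer_sizes", (64, 32))
        params.setdefault("max_iter", 500)
        return MLPClassifier(random_state=seed, **params)
    raise ValueError(f"unknown base algorithm tag {tag!r}")


def _build_meta(tag: str, seed: int, params: Mapping | None = None):
    params = dict(params or {})
    if tag == "LR":
        from sklearn.linear_model import LogisticRegression
        params.setdefault("max_iter", 2000)
        return LogisticRegression(random_state=seed, **params)
    if tag == "RF":
        from sklearn.ensemble import RandomForestClassifier
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if tag == "SVM":
        from sklearn.svm import SVC
        params.setdefault("probability", True)
        return SVC(random_state=seed, **params)
    raise ValueError(f"unknown meta tag {tag!r}; choose from {META_TAGS}")


def available_algorithms(algorithms: Sequence[str] = DEFAULT_ALGORITHMS) -> tuple[str, ...]:
    """The subset of base-learner tags whose backing libraries import.

    The default 12-slot layer needs xgboost, lightgbm and catboost; this
    helper gives the documented fallback spec for environments missing
    any of them.  Nothing is ever substituted silently — a spec naming an
    unavailable tag fails loudly at fit time.
    """
    out = []
    for tag in algorithms:
        try:
            _build_estimator(tag, 0)
        except ImportError:
            continue
        out.append(tag)
    return tuple(out)


@dataclass(frozen=True)
class BaseLayerSpec:
    """Which base algorithms to train, their params, fold plan and seed."""

    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS
    params: Mapping[str, Mapping] = field(default_factory=dict)
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "algorithms", tuple(self.algorithms))
        if len(set(self.algorithms)) != len(self.algorithms):
            raise ValueError("algorithm tags must be unique")
        if not self.algorithms:
            raise ValueError("at least one base algorithm required")


@dataclass
class BaseLayerFit:
    """Trained base bundle for one selector block."""

    spec: BaseLayerSpec
    models: dict[str, object]          # tag -> estimator refit on all rows
    oof: np.ndarray                    # n x n_algorithms out-of-fold P(PVP)
    fold_of_row: np.ndarray            # n, fold index holding each row out
    ids: tuple[str, ...]


@dataclass
class MetaBlock:
    """Out-of-fold (and optionally holdout) meta-features for one selector."""

    source_selector: str
    oof: np.ndarray
    column_names: tuple[str, ...]
    ids: tuple[str, ...]


def _fit(model, X: np.ndarray, y: np.ndarray):
    """Fit, silencing only the SVC(probability=True) deprecation notice.

    Platt-scaled SVC stays in use deliberately: the calibrated-CV
    replacement cannot fit the single-sample folds the base layer must
    support at small n.
    """
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*probability.*deprecated.*", category=FutureWarning
        )
        model.fit(X, y)
    return model


def _stratified_folds(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Shared fold plan: stratified when each class can reach every fold,
    plain shuffled folds otherwise (e.g. the n == folds leave-one-out
    boundary, where stratification is impossible by counting)."""
    from sklearn.model_selection import KFold, StratifiedKFold
    fold_of_row = np.full(len(y), -1, dtype=int)
    min_class = np.bincount(y).min()
    if min_class >= folds:
        kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for f, (_, test_idx) in enumerate(kf.split(np.zeros((len(y), 1)), y)):
        fold_of_row[test_idx] = f
    return fold_of_row


def _positive_proba(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    pos_col = list(model.classes_).index(1)
    return proba[:, pos_col]


def fit_base_layer(fm_reduced: FeatureMatrix, spec: BaseLayerSpec) -> tuple[BaseLayerFit, MetaBlock]:
    """Train the base layer on one reduced matrix with shared stratified folds.

    Every algorithm sees the same fold plan, so out-of-fold columns align
    row-by-row.  For each algorithm the fold-f model (trained on all other
    folds) predicts fold-f rows, and a final refit on all rows is stored
    for inference on new data.
    """
    y = fm_reduced.y
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("base layer needs both classes present")
    if fm_reduced.n < spec.folds:
        raise ValueError(f"n={fm_reduced.n} < folds={spec.folds}")
    # verify availability up front: no silent skips
    unavailable = []
    for tag in spec.algorithms:
        try:
            _build_estimator(tag, spec.seed)
        except ImportError as exc:
            unavailable.append(f"{tag} ({exc})")
    if unavailable:
        raise ImportError("unavailable base algorithms: " + "; ".join(unavailable))

    fold_of_row = _stratified_folds(y, spec.folds, spec.seed)
    for f in range(spec.folds):
        train_mask = fold_of_row != f
        if len(np.unique(y[train_mask])) < 2:
            raise ValueError(
                f"fold {f} leaves a single-class training set; use fewer folds"
            )

    X = fm_reduced.X
    oof = np.full((fm_reduced.n, len(spec.algorithms)), np.nan)
    models: dict[str, object] = {}
    for j, tag in enumerate(spec.algorithms):
        for f in range(spec.folds):
            test_mask = fold_of_row == f
            model = _build_estimator(tag, spec.seed, spec.params.get(tag))
            _fit(model, X[~test_mask], y[~test_mask])
            oof[test_mask, j] = _positive_proba(model, X[test_mask])
        final = _build_estimator(tag, spec.seed, spec.params.get(tag))
        _fit(final, X, y)
        models[tag] = final
    assert not np.isnan(oof).any(), "out-of-fold matrix has holes"

    fit = BaseLayerFit(spec, models, oof, fold_of_row, fm_reduced.ids)
    block = MetaBlock("", oof, tuple(spec.algorithms), fm_reduced.ids)
    return fit, block


def predict_base_layer(fit: BaseLayerFit, X: np.ndarray) -> np.ndarray:
    """Per-algorithm positive-class probabilities from the full-train refits."""
    return np.column_stack(
        [_positive_proba(fit.models[tag], X) for tag in fit.spec.algorithms]
    )


def assemble_meta_features(blocks: Mapping[str, MetaBlock]) -> FeatureMatrix:
    """Concatenate blocks column-wise in fixed selector order F, Var, RFECV.

    All blocks must share identical sample ids in identical order.
    Labels are not carried by blocks; attach them via
    :func:`meta_feature_matrix` when training.
    """
    if not blocks:
        raise ValueError("at least one meta block required")
    tags = [t for t in SELECTOR_ORDER if t in blocks]
    extra = set(blocks) - set(SELECTOR_ORDER)
    if extra:
        raise ValueError(f"unknown selector tags {sorted(extra)}")
    first = blocks[tags[0]]
    for t in tags[1:]:
        if blocks[t].ids != first.ids:
            raise ValueError(f"sample ids of block {t} disagree with block {tags[0]}")
    X = np.column_stack([blocks[t].oof for t in tags])
    names = tuple(f"{t}_{c}" for t in tags for c in blocks[t].column_names)
    return FeatureMatrix(first.ids, X, names, np.zeros(len(first.ids), dtype=int))


def meta_feature_matrix(blocks: Mapping[str, MetaBlock], y: np.ndarray) -> FeatureMatrix:
    fm = assemble_meta_features(blocks)
    return FeatureMatrix(fm.ids, fm.X, fm.names, y)


@dataclass
class StackedModel:
    """A trained two-layer stack plus the provenance to replay it."""

    blocks_used: tuple[str, ...]
    selections: dict[str, SelectionResult]
    base_fits: dict[str, BaseLayerFit]
    meta_tag: str
    meta_model: object
    meta_names: tuple[str, ...]
    seed: int
    threshold: float = 0.5

    def predict(self, fm: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Probabilities and labels for new samples.

        ``fm`` must carry the full (pre-selection) feature names; each
        block's stored selection subsets it, its base refits emit
        probabilities, and the meta model maps the concatenation to the
        final positive-class probability.  Label = probability >= threshold.
        """
        blocks = {}
        for tag in self.blocks_used:
            reduced = apply_selection(fm, self.selections[tag])
            probs = predict_base_layer(self.base_fits[tag], reduced.X)
            blocks[tag] = MetaBlock(tag, probs, self.base_fits[tag].spec.algorithms, fm.ids)
        meta_fm = assemble_meta_features(blocks)
        if meta_fm.names != self.meta_names:
            raise ValueError("meta-feature layout mismatch with the trained model")
        proba = _positive_proba(self.meta_model, meta_fm.X)
        return proba, (proba >= self.threshold).astype(int)

    def prediction_hash(self, fm: FeatureMatrix) -> str:
        """SHA-256 of the probability vector (reproducibility checks)."""
        proba, _ = self.predict(fm)
        return hashlib.sha256(np.round(proba, 12).tobytes()).hexdigest()


def fit_meta(
    meta_fm: FeatureMatrix, meta_tag: str, seed: int, params: Mapping | None = None
):
    """Train the second-layer classifier on out-of-fold meta-features."""
    model = _build_meta(meta_tag, seed, params)
    _fit(model, meta_fm.X, meta_fm.y)
    return model


def train_stacked(
    fm: FeatureMatrix,
    selections: Mapping[str, SelectionResult],
    blocks_used: Sequence[str],
    meta_tag: str,
    spec: BaseLayerSpec,
    threshold: float = 0.5,
) -> StackedModel:
    """Fit the full two-layer stack on a training matrix.

    ``selections`` maps selector tags to fitted SelectionResults over
    ``fm``'s features; ``blocks_used`` picks which blocks feed the meta
    layer (order normalized to F, Var, RFECV).
    """
    blocks_used = tuple(t for t in SELECTOR_ORDER if t in blocks_used)
    if not blocks_used:
        raise ValueError("blocks_used must name at least one selector")
    base_fits: dict[str, BaseLayerFit] = {}
    blocks: dict[str, MetaBlock] = {}
    for tag in blocks_used:
        reduced = apply_selection(fm, selections[tag])
        fit, block = fit_base_layer(reduced, spec)
        block.source_selector = tag
        base_fits[tag] = fit
        blocks[tag] = block
    meta_fm = meta_feature_matrix(blocks, fm.y)
    meta_model = fit_meta(meta_fm, meta_tag, spec.seed)
    return StackedModel(
        blocks_used=blocks_used,
        selections={t: selections[t] for t in blocks_used},
        base_fits=base_fits,
        meta_tag=meta_tag,
        meta_model=meta_model,
        meta_names=meta_fm.names,
        seed=spec.seed,
        threshold=threshold,
    )


def enumerate_grid() -> dict:
    """The experiment plan: 36 base models and 21 stacked configurations."""
    subsets = []
    for r in (1, 2, 3):
        subsets.extend(combinations(SELECTOR_ORDER, r))
    stacked = [(subset, meta) for meta in META_TAGS for subset in subsets]
    base = [(alg, sel) for alg in DEFAULT_ALGORITHMS for sel in SELECTOR_ORDER]
    assert len(subsets) == 7 and len(stacked) == 21 and len(base) == 36
    return {"block_subsets": subsets, "stacked": stacked, "base": base}


def combination_name(blocks: Sequence[str]) -> str:
    """Grid row label, e.g. ('F', 'RFECV') -> 'F_RFECV', all three -> 'All_three'."""
    blocks = tuple(t for t in SELECTOR_ORDER if t in blocks)
    if len(blocks) == 3:
        return "All_three"
    return "_".join(blocks)


def save_model(model: StackedModel, directory: str | Path) -> None:
    """Serialize a stacked model bundle: config snapshot + joblib payload."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "blocks_used": list(model.blocks_used),
        "meta_tag": model.meta_tag,
        "seed": model.seed,
        "threshold": model.threshold,
        "algorithms": {t: list(model.base_fits[t].spec.algorithms) for t in model.blocks_used},
        "folds": {t: model.base_fits[t].spec.folds for t in model.blocks_used},
        "selections": {
            t: {"method": s.method, "params": s.params, "n_kept": len(s.kept_names)}
            for t, s in model.selections.items()
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    for tag, sel in model.selections.items():
        sel.save(directory / f"selection_{tag}.tsv")
    joblib.dump(model, directory / "model.joblib")


def load_model(directory: str | Path) -> StackedModel:
    return joblib.load(Path(directory) / "model.joblib")
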