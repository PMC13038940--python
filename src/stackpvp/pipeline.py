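"""High-level orchestration: batch encoding, selector fitting, training,
evaluation and the experiment grid.

This layer glues the descriptor encoders, selectors and the stacked
ensemble into the end-to-end workflow: FASTA + PSSM directory in,
feature tables / trained model bundles / metric tables out.  The CLI is
a thin wrapper over these functions.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import MetricReport, evaluate_predictions
from .evolutionary_features import encode_evolutionary
from .feature_selection import (
    FeatureMatrix,
    SelectionResult,
    apply_selection,
    f_select,
    rfecv_select,
    variance_select,
)
from .pssm_io import PssmProfile
from .sequence_features import encode_sequence
from .sequence_io import ProteinRecord
from .stacking_ensemble import (
    SELECTOR_ORDER,
    BaseLayerSpec,
    StackedModel,
    combination_name,
    enumerate_grid,
    train_stacked,
)

logger = logging.getLogger(__name__)

#: Default retained count for the F-score selector (the study leaves the
#: retained dimensionalities unstated; this is an explicit, recorded default).
DEFAULT_F_TOP_K = 400

#: Variance threshold default: the 25th percentile of training feature variances.
DEFAULT_VAR_PERCENTILE = 25.0


def encode_dataset(
    records: Sequence[ProteinRecord],
    profiles: Mapping[str, PssmProfile] | None,
    labels: Mapping[str, int] | None,
    features: str = "evolutionary",
) -> FeatureMatrix:
    """Batch-encode records into a labeled feature matrix.

    ``features`` is ``evolutionary`` (860 PSSM-derived columns, requires a
    profile per record), ``sequence`` (723 classical columns) or ``both``
    (1583).  Records missing a profile raise, naming the ids.
    """
    if features not in ("evolutionary", "sequence", "both"):
        raise ValueError(f"unknown feature family {features!r}")
    need_pssm = features in ("evolutionary", "both")
    if need_pssm:
        if profiles is None:
            raise ValueError("evolutionary features require PSSM profiles")
        missing = [r.id for r in records if r.id not in profiles]
        if missing:
            raise KeyError(f"missing PSSM profiles for ids: {', '.join(missing)}")
    rows, names = [], None
    for rec in records:
        parts = []
        if need_pssm:
            parts.append(encode_evolutionary(profiles[rec.id]))
        if features in ("sequence", "both"):
            parts.append(encode_sequence(rec))
        vals = np.concatenate([p.values for p in parts])
        row_names = tuple(n for p in parts for n in p.names)
        if names is None:
            names = row_names
        rows.append(vals)
    y = np.array([labels[r.id] for r in records]) if labels is not None else np.zeros(len(records), dtype=int)
    return FeatureMatrix(tuple(r.id for r in records), np.array(rows), names, y)


def fit_selectors(
    fm: FeatureMatrix,
    f_top_k: int = DEFAULT_F_TOP_K,
    var_percentile: float = DEFAULT_VAR_PERCENTILE,
    rfecv_estimator: str = "linear-svm",
    rfecv_folds: int = 10,
    rfecv_step: int = 1,
    seed: int = 0,
    which: Sequence[str] = SELECTOR_ORDER,
) -> dict[str, SelectionResult]:
    """Fit the requested selectors on a training matrix.

    The variance threshold is the ``var_percentile``-th percentile of the
    training feature variances (recorded in the result's params).
    """
    out: dict[str, SelectionResult] = {}
    for tag in which:
        t0 = time.perf_counter()
        if tag == "F":
            out[tag] = f_select(fm, min(f_top_k, fm.d))
        elif tag == "Var":
            threshold = float(np.percentile(fm.X.var(axis=0), var_percentile))
            sel = variance_select(fm, threshold)
            sel.params["percentile"] = var_percentile
            out[tag] = sel
        elif tag == "RFECV":
            out[tag] = rfecv_select(
                fm, estimator_tag=rfecv_estimator, cv_folds=rfecv_folds,
                step=rfecv_step, seed=seed,
            )
        else:
            raise ValueError(f"unknown selector tag {tag!r}")
        logger.info(
            "selector %s kept %d/%d features in %.1fs",
            tag, len(out[tag].kept_names), fm.d, time.perf_counter() - t0,
        )
    return out


def train_and_evaluate(
    train_fm: FeatureMatrix,
    test_fm: FeatureMatrix,
    selections: Mapping[str, SelectionResult],
    blocks: Sequence[str],
    meta_tag: str,
    spec: BaseLayerSpec,
) -> tuple[StackedModel, MetricReport]:
    """Fit one stacked configuration and score it on the held-out matrix."""
    model = train_stacked(train_fm, selections, blocks, meta_tag, spec)
    proba, _ = model.predict(test_fm)
    return model, evaluate_predictions(test_fm.y, proba, model.threshold)


def run_grid(
    train_fm: FeatureMatrix,
    test_fm: FeatureMatrix,
    selections: Mapping[str, SelectionResult],
    spec: BaseLayerSpec,
) -> pd.DataFrame:
    """The full 21-configuration stacked grid, one metric row per model.

    Rows mirror the study layout: meta-classifier x block combination,
    with ACC, Sn, Sp, Precision, F1, MCC and ROC AUC on the test set.
    """
    plan = enumerate_grid()
    rows = []
    for subset, meta in plan["stacked"]:
        _, rep = train_and_evaluate(train_fm, test_fm, selections, subset, meta, spec)
        rows.append({
            "meta": meta,
            "dataset": combination_name(subset),
            **{k: v for k, v in rep.as_dict().items() if k != "balanced_auc"},
        })
        logger.info("grid %s/%s done", meta, combination_name(subset))
    return pd.DataFrame(rows)
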