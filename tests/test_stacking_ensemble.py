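import numpy as np
import pytest

from stackpvp.evaluation import evaluate_predictions, roc_auc
from stackpvp.feature_selection import FeatureMatrix, SelectionResult
from stackpvp.stacking_ensemble import (
    DEFAULT_ALGORITHMS,
    META_TAGS,
    SELECTOR_ORDER,
    BaseLayerSpec,
    MetaBlock,
    assemble_meta_features,
    available_algorithms,
    combination_name,
    enumerate_grid,
    fit_base_layer,
    fit_meta,
    load_model,
    meta_feature_matrix,
    save_model,
    train_stacked,
    _build_estimator,
)

FAST_ALGOS = ("DT", "RF", "KNN", "SVM")


def gaussian_fm(rng, n=60, d=6, delta=5.0, ids_prefix="s"):
    """Two spherical Gaussians separated by delta sd along every axis."""
    n_pos = n // 2
    y = np.r_[np.zeros(n - n_pos, dtype=int), np.ones(n_pos, dtype=int)]
    X = rng.normal(size=(n, d)) + delta * y[:, None]
    return FeatureMatrix(
        tuple(f"{ids_prefix}{i}" for i in range(n)), X, tuple(f"f{i}" for i in range(d)), y
    )


def identity_selection(fm, method="F"):
    return SelectionResult(method, fm.names)


class TestFitBaseLayer:
    def test_separable_data_every_algorithm_accurate(self, rng):
        fm = gaussian_fm(np.random.default_rng(7), n=100, delta=5.0)
        spec = BaseLayerSpec(algorithms=available_algorithms(), folds=5, seed=7)
        fit, block = fit_base_layer(fm, spec)
        for j, tag in enumerate(spec.algorithms):
            acc = np.mean((block.oof[:, j] >= 0.5) == fm.y)
            assert acc >= 0.9, f"{tag} out-of-fold accuracy {acc:.2f}"
        assert ((block.oof >= 0) & (block.oof <= 1)).all()

    def test_n_equals_folds_boundary(self, rng):
        fm = gaussian_fm(rng, n=10, delta=4.0)
        spec = BaseLayerSpec(algorithms=("DT", "KNN"), folds=10, seed=0)
        fit, block = fit_base_layer(fm, spec)
        assert not np.isnan(block.oof).any()
        assert sorted(np.bincount(fit.fold_of_row)) == [1] * 10

    def test_same_seed_gives_bitwise_identical_oof(self, rng):
        fm = gaussian_fm(rng, n=40, delta=2.0)
        spec = BaseLayerSpec(
            algorithms=("DT", "RF", "XGBoost", "LightGBM"), folds=5, seed=13
        )
        _, a = fit_base_layer(fm, spec)
        _, b = fit_base_layer(fm, spec)
        np.testing.assert_array_equal(a.oof, b.oof)

    def test_out_of_fold_bookkeeping_excludes_own_row(self, rng):
        """Rebuilding a fold model without a row reproduces that row's value."""
        fm = gaussian_fm(rng, n=30, delta=2.0)
        spec = BaseLayerSpec(algorithms=("DT",), folds=5, seed=4)
        fit, block = fit_base_layer(fm, spec)
        row = 17
        f = fit.fold_of_row[row]
        train_mask = fit.fold_of_row != f
        assert not train_mask[row]  # the row is excluded from its fold model
        model = _build_estimator("DT", spec.seed)
        model.fit(fm.X[train_mask], fm.y[train_mask])
        pos = list(model.classes_).index(1)
        assert model.predict_proba(fm.X[row : row + 1])[0, pos] == block.oof[row, 0]

    def test_unavailable_backend_errors_loudly(self, rng):
        try:
            import catboost  # noqa: F401
        except ImportError:
            fm = gaussian_fm(rng, n=20)
            spec = BaseLayerSpec(algorithms=("DT", "CatBoost"), folds=5, seed=0)
            with pytest.raises(ImportError, match="CatBoost"):
                fit_base_layer(fm, spec)

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError, match="unknown base algorithm"):
            _build_estimator("Perceptron9000", 0)

    def test_single_class_rejected(self, rng):
        fm = FeatureMatrix(("a", "b"), np.zeros((2, 2)), ("f0", "f1"), np.array([1, 1]))
        with pytest.raises(ValueError, match="both classes"):
            fit_base_layer(fm, BaseLayerSpec(algorithms=("DT",), folds=2))


class TestAssembleMetaFeatures:
    @staticmethod
    def _block(rng, tag, ids, algos=DEFAULT_ALGORITHMS):
        return MetaBlock(tag, rng.random((len(ids), len(algos))), tuple(algos), ids)

    def test_widths_12_24_36(self, rng):
        ids = tuple(f"s{i}" for i in range(5))
        blocks = {t: self._block(rng, t, ids) for t in SELECTOR_ORDER}
        assert assemble_meta_features({"F": blocks["F"]}).d == 12
        assert assemble_meta_features({"F": blocks["F"], "RFECV": blocks["RFECV"]}).d == 24
        assert assemble_meta_features(blocks).d == 36

    def test_fixed_selector_order(self, rng):
        ids = ("a", "b")
        blocks = {t: self._block(rng, t, ids, algos=("DT",)) for t in ("RFECV", "F")}
        fm = assemble_meta_features(blocks)
        assert fm.names == ("F_DT", "RFECV_DT")

    def test_id_mismatch_rejected(self, rng):
        b1 = self._block(rng, "F", ("a", "b"), algos=("DT",))
        b2 = self._block(rng, "Var", ("b", "a"), algos=("DT",))
        with pytest.raises(ValueError, match="ids"):
            assemble_meta_features({"F": b1, "Var": b2})


class TestMeta:
    def test_rf_meta_on_separable_meta_features(self, rng):
        ids = tuple(f"s{i}" for i in range(60))
        y = np.r_[np.zeros(30, dtype=int), np.ones(30, dtype=int)]
        oof = np.clip(0.5 + 0.4 * (2 * y[:, None] - 1) + rng.normal(0, 0.05, (60, 12)), 0, 1)
        block = MetaBlock("F", oof, DEFAULT_ALGORITHMS, ids)
        meta_fm = meta_feature_matrix({"F": block}, y)
        model = fit_meta(meta_fm, "RF", seed=0)
        proba = model.predict_proba(meta_fm.X)[:, 1]
        auc, *_ = roc_auc(y, proba)
        assert auc >= 0.95

    def test_constant_meta_features_give_majority_and_half_auc(self):
        ids = tuple(f"s{i}" for i in range(20))
        y = np.r_[np.zeros(8, dtype=int), np.ones(12, dtype=int)]
        block = MetaBlock("F", np.full((20, 12), 0.5), DEFAULT_ALGORITHMS, ids)
        meta_fm = meta_feature_matrix({"F": block}, y)
        model = fit_meta(meta_fm, "RF", seed=0)
        pred = model.predict(meta_fm.X)
        assert (pred == 1).all()  # majority class
        auc, *_ = roc_auc(y, model.predict_proba(meta_fm.X)[:, 1])
        assert auc == 0.5

    def test_unknown_meta_tag(self, rng):
        ids = ("a", "b", "c", "d")
        block = MetaBlock("F", np.random.rand(4, 2), ("DT", "RF"), ids)
        meta_fm = meta_feature_matrix({"F": block}, np.array([0, 1, 0, 1]))
        with pytest.raises(ValueError, match="meta tag"):
            fit_meta(meta_fm, "NB", seed=0)


class TestStackedModel:
    @staticmethod
    def _train(rng, delta=3.0, n=50, meta="RF"):
        fm = gaussian_fm(rng, n=n, delta=delta)
        sels = {"F": identity_selection(fm, "F"), "RFECV": identity_selection(fm, "RFECV")}
        spec = BaseLayerSpec(algorithms=FAST_ALGOS, folds=5, seed=21)
        model = train_stacked(fm, sels, ("F", "RFECV"), meta, spec)
        return fm, model

    def test_probability_bounds_and_threshold_labels(self, rng):
        fm, model = self._train(rng)
        proba, labels = model.predict(fm)
        assert ((proba >= 0) & (proba <= 1)).all()
        np.testing.assert_array_equal(labels, (proba >= 0.5).astype(int))

    def test_training_repredict_at_least_oof_accurate(self, rng):
        fm, model = self._train(rng, delta=2.0, n=60)
        proba, labels = model.predict(fm)
        train_acc = np.mean(labels == fm.y)
        oof_block = model.base_fits["F"].oof
        oof_acc = np.mean(
            [np.mean((oof_block[:, j] >= 0.5) == fm.y) for j in range(oof_block.shape[1])]
        )
        assert train_acc >= oof_acc - 1e-12  # refit optimism

    def test_batch_equals_per_sample_loop(self, rng):
        fm, model = self._train(rng)
        batch, _ = model.predict(fm)
        singles = []
        for i in range(fm.n):
            sub = FeatureMatrix((fm.ids[i],), fm.X[i : i + 1], fm.names, fm.y[i : i + 1])
            singles.append(model.predict(sub)[0][0])
        np.testing.assert_allclose(batch, singles)

    def test_pinned_seed_reproduces_prediction_hash(self, rng):
        state = rng.bit_generator.state
        fm1, model1 = self._train(np.random.default_rng(99))
        fm2, model2 = self._train(np.random.default_rng(99))
        assert model1.prediction_hash(fm1) == model2.prediction_hash(fm2)

    def test_stacking_not_worse_than_mean_base(self, rng):
        train = gaussian_fm(np.random.default_rng(5), n=80, delta=3.0)
        test = gaussian_fm(np.random.default_rng(55), n=80, delta=3.0, ids_prefix="t")
        sels = {"F": identity_selection(train)}
        spec = BaseLayerSpec(algorithms=FAST_ALGOS, folds=5, seed=5)
        model = train_stacked(train, sels, ("F",), "RF", spec)
        proba, _ = model.predict(test)
        stacked_auc, *_ = roc_auc(test.y, proba)
        from stackpvp.stacking_ensemble import predict_base_layer
        base_probs = predict_base_layer(model.base_fits["F"], test.X)
        base_aucs = [roc_auc(test.y, base_probs[:, j])[0] for j in range(base_probs.shape[1])]
        assert stacked_auc >= np.mean(base_aucs) - 0.02

    def test_save_load_round_trip(self, rng, tmp_path):
        fm, model = self._train(rng)
        save_model(model, tmp_path / "bundle")
        back = load_model(tmp_path / "bundle")
        np.testing.assert_array_equal(back.predict(fm)[0], model.predict(fm)[0])
        assert (tmp_path / "bundle" / "manifest.json").exists()
        assert (tmp_path / "bundle" / "selection_F.tsv").exists()


class TestGrid:
    def test_seven_block_subsets(self):
        plan = enumerate_grid()
        assert len(plan["block_subsets"]) == 7 == 2**3 - 1

    def test_twenty_one_stacked_configurations(self):
        assert len(enumerate_grid()["stacked"]) == 21

    def test_thirty_six_base_models(self):
        plan = enumerate_grid()
        assert len(plan["base"]) == 36
        assert len(DEFAULT_ALGORITHMS) == 12 and len(META_TAGS) == 3

    def test_combination_names(self):
        assert combination_name(("F", "RFECV")) == "F_RFECV"
        assert combination_name(("RFECV", "F")) == "F_RFECV"  # order normalized
        assert combination_name(SELECTOR_ORDER) == "All_three"
        assert combination_name(("Var",)) == "Var"
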