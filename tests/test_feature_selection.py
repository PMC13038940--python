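import numpy as np
import pytest
from sklearn.feature_selection import VarianceThreshold, f_classif

from stackpvp.feature_selection import (
    FeatureMatrix,
    SelectionResult,
    apply_selection,
    f_score_rank,
    f_select,
    rfecv_select,
    variance_select,
)


def make_fm(X, y, names=None, ids=None):
    X = np.asarray(X, dtype=float)
    names = names or tuple(f"f{i}" for i in range(X.shape[1]))
    ids = ids or tuple(f"s{i}" for i in range(X.shape[0]))
    return FeatureMatrix(ids, X, names, y)


@pytest.fixture
def random_fm(rng):
    X = rng.normal(size=(30, 8))
    y = np.r_[np.zeros(15, dtype=int), np.ones(15, dtype=int)]
    return make_fm(X, y)


class TestFScore:
    def test_constant_feature_scores_zero(self):
        X = np.column_stack([np.ones(10), np.r_[np.zeros(5), np.ones(5)]])
        fm = make_fm(X, np.r_[np.zeros(5, dtype=int), np.ones(5, dtype=int)])
        F = f_score_rank(fm)
        assert F[0] == 0.0

    def test_perfect_separation_infinite(self):
        X = np.r_[np.zeros(5), np.ones(5)].reshape(-1, 1)
        fm = make_fm(X, np.r_[np.zeros(5, dtype=int), np.ones(5, dtype=int)])
        assert np.isinf(f_score_rank(fm)[0])

    def test_matches_anova_oracle_and_sklearn(self, rng):
        for _ in range(100):
            n0, n1 = int(rng.integers(3, 15)), int(rng.integers(3, 15))
            X = rng.normal(size=(n0 + n1, 5))
            y = np.r_[np.zeros(n0, dtype=int), np.ones(n1, dtype=int)]
            fm = make_fm(X, y)
            F = f_score_rank(fm)
            # hand-rolled two-group ANOVA
            for j in range(5):
                a, b = X[y == 0, j], X[y == 1, j]
                grand = X[:, j].mean()
                msb = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
                msw = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (
                    len(X) - 2
                )
                assert F[j] == pytest.approx(msb / msw, rel=1e-10)
            np.testing.assert_allclose(F, f_classif(X, y)[0], rtol=1e-8)

    def test_single_class_rejected(self):
        fm = make_fm(np.zeros((4, 2)), np.zeros(4, dtype=int))
        with pytest.raises(ValueError, match="both classes"):
            f_score_rank(fm)


class TestFSelect:
    def test_k_equals_d_orders_by_f_descending(self, random_fm):
        sel = f_select(random_fm, random_fm.d)
        F = f_score_rank(random_fm)
        expect = [random_fm.names[i] for i in np.lexsort((np.arange(random_fm.d), -F))]
        assert list(sel.kept_names) == expect

    def test_informative_feature_wins(self, rng):
        # one feature with a 3-sd class shift among pure noise, n = 200
        n = 200
        y = np.r_[np.zeros(n // 2, dtype=int), np.ones(n // 2, dtype=int)]
        X = rng.normal(size=(n, 10))
        X[:, 4] += 3.0 * y
        sel = f_select(make_fm(X, y), 1)
        assert sel.kept_names == ("f4",)

    def test_all_constant_ties_break_by_index(self):
        fm = make_fm(np.ones((6, 5)), np.r_[np.zeros(3, dtype=int), np.ones(3, dtype=int)])
        sel = f_select(fm, 3)
        assert sel.kept_names == ("f0", "f1", "f2")

    def test_k_out_of_range(self, random_fm):
        with pytest.raises(ValueError):
            f_select(random_fm, random_fm.d + 1)


class TestVarianceSelect:
    def test_constant_feature_removed(self):
        X = np.column_stack([np.ones(6), np.arange(6)])
        fm = make_fm(X, np.r_[np.zeros(3, dtype=int), np.ones(3, dtype=int)])
        sel = variance_select(fm, 1e-9)
        assert sel.kept_names == ("f1",)

    def test_threshold_zero_keeps_all(self, random_fm):
        assert variance_select(random_fm, 0.0).kept_names == random_fm.names

    def test_matches_brute_scan_and_sklearn(self, rng):
        X = rng.normal(size=(25, 12)) * rng.uniform(0.1, 3.0, size=12)
        fm = make_fm(X, np.r_[np.zeros(13, dtype=int), np.ones(12, dtype=int)])
        threshold = float(np.median(X.var(axis=0)))
        sel = variance_select(fm, threshold)
        expect = tuple(fm.names[j] for j in range(12) if X[:, j].var() >= threshold)
        assert sel.kept_names == expect
        skl = VarianceThreshold(threshold * (1 - 1e-12)).fit(X)
        assert list(sel.kept_names) == [fm.names[j] for j in np.flatnonzero(skl.get_support())]

    def test_negative_threshold_rejected(self, random_fm):
        with pytest.raises(ValueError, match="non-negative"):
            variance_select(random_fm, -0.1)


class TestRfecv:
    def test_single_feature_kept(self, rng):
        X = rng.normal(size=(30, 1))
        y = np.r_[np.zeros(15, dtype=int), np.ones(15, dtype=int)]
        sel = rfecv_select(make_fm(X, y), cv_folds=5, seed=0)
        assert sel.kept_names == ("f0",)

    def test_recovers_informative_features(self, rng):
        # 3 informative (2-sd shift) + 17 noise features, n = 300
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            y = np.r_[np.zeros(150, dtype=int), np.ones(150, dtype=int)]
            X = r.normal(size=(300, 20))
            for j in (2, 9, 17):
                X[:, j] += 2.0 * y
            sel = rfecv_select(make_fm(X, y), cv_folds=5, seed=seed)
            if {"f2", "f9", "f17"} <= set(sel.kept_names):
                hits += 1
        assert hits >= 18  # >= 90% of replicates

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(40, 6))
        y = np.r_[np.zeros(20, dtype=int), np.ones(20, dtype=int)]
        fm = make_fm(X, y)
        a = rfecv_select(fm, cv_folds=4, seed=11)
        b = rfecv_select(fm, cv_folds=4, seed=11)
        assert a.kept_names == b.kept_names

    def test_unknown_estimator_tag(self, random_fm):
        with pytest.raises(ValueError, match="estimator tag"):
            rfecv_select(random_fm, estimator_tag="kmeans", cv_folds=3)


class TestApplySelection:
    def test_keep_all_is_identity(self, random_fm):
        sel = SelectionResult("Var", random_fm.names)
        out = apply_selection(random_fm, sel)
        np.testing.assert_array_equal(out.X, random_fm.X)
        assert out.names == random_fm.names

    def test_column_permutation_oracle(self, rng, random_fm):
        sel = f_select(random_fm, 4)
        perm = rng.permutation(random_fm.d)
        shuffled = FeatureMatrix(
            random_fm.ids,
            random_fm.X[:, perm],
            tuple(random_fm.names[i] for i in perm),
            random_fm.y,
        )
        a = apply_selection(random_fm, sel)
        b = apply_selection(shuffled, sel)
        np.testing.assert_array_equal(a.X, b.X)
        assert a.names == b.names == sel.kept_names

    def test_missing_feature_error_lists_name(self, random_fm):
        sel = SelectionResult("F", ("f0", "nope"))
        with pytest.raises(KeyError, match="nope"):
            apply_selection(random_fm, sel)

    def test_no_refit_on_held_out_data(self, rng, random_fm):
        """Leakage guard: selection fit on train applies verbatim to new data."""
        sel = f_select(random_fm, 3)
        held_out = FeatureMatrix(
            ("h0", "h1"), rng.normal(size=(2, random_fm.d)), random_fm.names,
            np.array([0, 1]),
        )
        out = apply_selection(held_out, sel)
        assert out.names == sel.kept_names  # exactly the train-time choice
        cols = [random_fm.names.index(n) for n in sel.kept_names]
        np.testing.assert_array_equal(out.X, held_out.X[:, cols])


def test_selection_result_round_trip(tmp_path, random_fm):
    sel = f_select(random_fm, 5)
    path = tmp_path / "sel.tsv"
    sel.save(path)
    back = SelectionResult.load(path)
    assert back.method == sel.method
    assert back.kept_names == sel.kept_names
    assert back.params == sel.params
    for name in sel.kept_names:
        assert back.scores[name] == pytest.approx(sel.scores[name])


def test_feature_matrix_frame_round_trip(random_fm):
    back = FeatureMatrix.from_frame(random_fm.to_frame())
    np.testing.assert_array_equal(back.X, random_fm.X)
    assert back.ids == random_fm.ids and back.names == random_fm.names
    np.testing.assert_array_equal(back.y, random_fm.y)
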