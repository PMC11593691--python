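import numpy as np
import pytest

from tanspec.errors import (
    DataError,
    DegenerateTargetError,
    InvalidLabelsError,
    InvalidParameterError,
)
from tanspec.models import (
    PLSModel,
    fit_bpnn,
    fit_plsda,
    fit_plsr,
    fit_rf,
    fit_svm,
    select_plsr_lv,
)


class TestPLSR:
    def test_single_channel_equals_simple_regression(self, rng):
        x = rng.normal(size=(30, 1))
        y = 2.5 * x[:, 0] + 1.0 + rng.normal(size=30) * 0.1
        m = fit_plsr(x, y, 1)
        slope, intercept = np.polyfit(x[:, 0], y, 1)
        assert m.coefficients[0, 0] == pytest.approx(slope, rel=1e-10)
        assert m.intercept[0] == pytest.approx(intercept, rel=1e-10)

    def test_full_rank_matches_least_squares(self, rng):
        X = rng.normal(size=(25, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=25) * 0.3
        m = fit_plsr(X, y, 6)
        D = np.hstack([np.ones((25, 1)), X])
        beta = np.linalg.lstsq(D, y, rcond=None)[0]
        fitted_ls = D @ beta
        assert np.allclose(m.predict(X), fitted_ls, rtol=1e-6)

    def test_rank_r_noiseless_residual_vanishes(self, rng):
        basis = rng.normal(size=(4, 12))
        scores = rng.normal(size=(40, 4))
        X = scores @ basis  # rank 4
        y = X @ rng.normal(size=12)  # in the row space
        m = fit_plsr(X, y, 4)
        assert np.max(np.abs(m.predict(X) - y)) < 1e-8

    def test_orthogonal_target_gives_null_model(self):
        # y orthogonal to the single centered channel -> coefficients ~ 0
        x = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # centered, orthogonal to x
        with pytest.raises(DegenerateTargetError):
            fit_plsr(x, y, 1)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(30, 15))
        y = rng.normal(size=30)
        m = fit_plsr(X, y, 8)
        G = m.x_scores.T @ m.x_scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) / np.max(np.diag(G)) < 1e-8

    def test_predicting_training_mean_input_gives_mean_response(self, rng):
        X = rng.normal(size=(20, 9))
        y = rng.normal(size=20)
        m = fit_plsr(X, y, 3)
        assert m.predict(X.mean(axis=0)) == pytest.approx(y.mean())

    def test_rmsec_non_increasing_in_lv(self, rng):
        X = rng.normal(size=(40, 20))
        y = X @ rng.normal(size=20) + rng.normal(size=40)
        prev = np.inf
        for k in range(1, 12):
            m = fit_plsr(X, y, k)
            rmsec = np.sqrt(np.mean((m.predict(X) - y) ** 2))
            assert rmsec <= prev + 1e-10
            prev = rmsec

    def test_lv_out_of_range_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        with pytest.raises(InvalidParameterError):
            fit_plsr(X, rng.normal(size=10), 10)

    def test_constant_target_rejected(self, rng):
        with pytest.raises(DegenerateTargetError):
            fit_plsr(rng.normal(size=(10, 4)), np.ones(10), 2)

    def test_json_roundtrip(self, rng, tmp_path):
        X = rng.normal(size=(15, 6))
        m = fit_plsr(X, rng.normal(size=15), 3)
        m.to_json(tmp_path / "pls.json")
        m2 = PLSModel.from_json(tmp_path / "pls.json")
        assert np.allclose(m.predict(X), m2.predict(X))

    def test_cv_lv_selection_prefers_true_dimension(self, rng):
        basis = rng.normal(size=(3, 25))
        X = rng.normal(size=(80, 3)) @ basis + rng.normal(size=(80, 25)) * 0.01
        y = X @ rng.normal(size=25) + rng.normal(size=80) * 0.05
        best, rmse = select_plsr_lv(X, y, range(1, 10), seed=1)
        assert best <= 5  # no need for more LVs than the true rank + noise


class TestPLSDA:
    def _toy(self, rng, sep=4.0, n=30):
        X = np.vstack(
            [rng.normal(size=(n, 6)), rng.normal(size=(n, 6)) + [sep, 0, 0, 0, 0, 0]]
        )
        labels = np.array(["a"] * n + ["b"] * n)
        return X, labels

    def test_separable_classes_perfect_accuracy(self, rng):
        X, labels = self._toy(rng, sep=8.0)
        clf = fit_plsda(X, labels, lv_range=range(1, 5), cv_folds=3, seed=0)
        assert (clf.predict(X) == labels).all()
        assert max(clf.cv_accuracy.values()) == 1.0

    def test_permuted_labels_near_chance(self, rng):
        X = rng.normal(size=(100, 10))
        labels = np.array(["a", "b"] * 50)
        perm = np.random.default_rng(3).permutation(100)
        clf = fit_plsda(X, labels[perm], lv_range=range(1, 4), cv_folds=5, seed=0)
        acc = max(clf.cv_accuracy.values())
        # binomial null: 0.5 +/- a few sd (sd ~ 0.05 at n=100)
        assert acc < 0.5 + 4 * 0.05

    def test_duplicated_training_set_same_model(self, rng):
        X, labels = self._toy(rng)
        c1 = fit_plsda(X, labels, lv_range=range(1, 4), cv_folds=3, seed=0)
        c2 = fit_plsda(
            np.vstack([X, X]), np.concatenate([labels, labels]),
            lv_range=range(1, 4), cv_folds=3, seed=0,
        )
        assert c1.n_lv == c2.n_lv
        assert np.allclose(c1.pls.coefficients, c2.pls.coefficients)

    def test_two_class_argmax_equals_indicator_threshold(self, rng):
        X, labels = self._toy(rng, sep=2.0)
        clf = fit_plsda(X, labels, lv_range=range(1, 4), cv_folds=3, seed=0)
        ind = clf.predict_indicator(X)
        by_threshold = np.where(ind[:, 0] >= ind[:, 1], clf.classes[0], clf.classes[1])
        assert (clf.predict(X) == by_threshold).all()

    def test_predicts_only_training_labels(self, rng):
        X, labels = self._toy(rng)
        clf = fit_plsda(X, labels, lv_range=range(1, 3), cv_folds=3, seed=0)
        assert set(clf.predict(rng.normal(size=(20, 6)))) <= set(labels)

    def test_single_class_rejected(self, rng):
        with pytest.raises(InvalidLabelsError):
            fit_plsda(rng.normal(size=(10, 4)), np.array(["a"] * 10))

    def test_class_smaller_than_folds_rejected(self, rng):
        labels = np.array(["a"] * 8 + ["b"] * 2)
        with pytest.raises(InvalidLabelsError):
            fit_plsda(rng.normal(size=(10, 4)), labels, cv_folds=5)


class TestBPNN:
    def test_linear_target_learned(self, rng):
        X = rng.normal(size=(200, 3))
        y = X @ np.array([2.0, -1.0, 0.5]) + 3.0
        model = fit_bpnn(X, y, hidden_nodes=10, epochs=500, seed=0)
        X_test = rng.normal(size=(50, 3))
        y_test = X_test @ np.array([2.0, -1.0, 0.5]) + 3.0
        pred = model.predict(X_test)
        r2 = np.corrcoef(y_test, pred)[0, 1] ** 2
        assert r2 > 0.99

    def test_constant_target_reproduced(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.full(30, 5.0)
        model = fit_bpnn(X, y, seed=0)
        assert np.max(np.abs(model.predict(X) - 5.0)) < 1e-6

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        p1 = fit_bpnn(X, y, seed=7).predict(X)
        p2 = fit_bpnn(X, y, seed=7).predict(X)
        assert np.array_equal(p1, p2)

    def test_nonfinite_input_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        X[0, 0] = np.nan
        with pytest.raises(DataError):
            fit_bpnn(X, rng.normal(size=10))


class TestSVMAndRF:
    def test_svm_separable_training_accuracy(self, rng):
        X = np.vstack([rng.normal(size=(25, 4)), rng.normal(size=(25, 4)) + 6])
        labels = np.array(["p"] * 25 + ["q"] * 25)
        clf = fit_svm(X, labels)
        assert (clf.predict(X) == labels).all()

    def test_rf_learns_step_function(self, rng):
        X = rng.uniform(-1, 1, size=(300, 5))
        y = np.where(X[:, 2] > 0.2, 3.0, -1.0)
        model = fit_rf(X[:200], y[:200], n_trees=200, seed=0)
        pred = model.predict(X[200:])
        r2 = np.corrcoef(y[200:], pred)[0, 1] ** 2
        assert r2 > 0.9

    def test_rf_ensemble_beats_single_tree(self, rng):
        X = rng.normal(size=(300, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=300) * 1.0
        tr, te = slice(0, 200), slice(200, 300)

        def rmse(n_trees):
            m = fit_rf(X[tr], y[tr], n_trees=n_trees, seed=0)
            return np.sqrt(np.mean((m.predict(X[te]) - y[te]) ** 2))

        assert rmse(500) <= rmse(1)

    def test_svm_single_class_rejected(self, rng):
        with pytest.raises(InvalidLabelsError):
            fit_svm(rng.normal(size=(10, 3)), np.array(["a"] * 10))
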