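"""Sparse PLS-DA estimator, tuning loop and SVM baseline."""

import numpy as np
import pytest

from discradiomics.splsda import SPLSDA, ber, svm_baseline, tune_splsda


def _planted_data(rng, n=200, p=50, n_classes=4, informative=(0, 1), sep=3.0):
    """Class-marker design: feature ``informative[j]`` is elevated in class j."""
    y = rng.integers(0, n_classes, n)
    X = rng.normal(size=(n, p))
    for j, feat in enumerate(informative):
        X[:, feat] += sep * (y == j) - sep * (y == (j + 1) % n_classes)
    return X, y + 2  # grades 2..5


class TestDenseEquivalence:
    def test_matches_svd_oracle(self):
        # with keepX = p each weight vector is the dominant left singular
        # vector of the deflated cross-covariance; check against direct SVD
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 6))
        y = rng.integers(0, 3, 30)
        res = SPLSDA(X, y, n_components=2).fit()
        Xc = (X - X.mean(0)) / X.std(0, ddof=1)
        Y = (y[:, None] == np.unique(y)[None, :]).astype(float)
        Yc = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        for h in range(2):
            u, s, vt = np.linalg.svd(Xc.T @ Yc, full_matrices=False)
            w = u[:, 0]
            got = res.x_weights[:, h]
            sign = np.sign(w @ got)
            np.testing.assert_allclose(got, sign * w, atol=1e-8)
            t = Xc @ got
            Xc = Xc - np.outer(t, Xc.T @ t / (t @ t))
            Yc = Yc - np.outer(t, Yc.T @ t / (t @ t))

    def test_matches_sklearn_pls(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 8))
        y = rng.integers(0, 3, 40)
        Y = (y[:, None] == np.unique(y)[None, :]).astype(float)
        res = SPLSDA(X, y, n_components=3).fit()
        pls = PLSRegression(n_components=3, scale=True).fit(X, Y)
        for h in range(3):
            a, b = res.x_weights[:, h], pls.x_weights_[:, h]
            sign = np.sign(a @ b)
            np.testing.assert_allclose(a, sign * b, atol=1e-3)


class TestSparsity:
    def test_keepx_bounds_nonzeros(self):
        rng = np.random.default_rng(2)
        X, y = _planted_data(rng)
        res = SPLSDA(X, y, n_components=2, keep_x=[3, 7]).fit()
        assert np.count_nonzero(res.x_weights[:, 0]) <= 3
        assert np.count_nonzero(res.x_weights[:, 1]) <= 7
        np.testing.assert_allclose(np.linalg.norm(res.x_weights, axis=0), 1.0)

    def test_planted_features_recovered(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            X, y = _planted_data(rng, n=160)
            res = SPLSDA(X, y, n_components=1, keep_x=2).fit()
            if set(res.selected_features(0)) == {0, 1}:
                hits += 1
        assert hits >= 95

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X, y = _planted_data(rng, n=80)
        perm = rng.permutation(80)
        a = SPLSDA(X, y, n_components=2, keep_x=5).fit()
        b = SPLSDA(X[perm], y[perm], n_components=2, keep_x=5).fit()
        np.testing.assert_allclose(a.x_weights, b.x_weights, atol=1e-7)

    def test_keepx_clipped_with_warning(self):
        rng = np.random.default_rng(4)
        X, y = _planted_data(rng, n=60, p=10)
        with pytest.warns(UserWarning):
            SPLSDA(X, y, n_components=1, keep_x=99)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            SPLSDA(np.zeros((10, 3)), np.full(10, 2))


class TestPrediction:
    def test_separable_training_accuracy(self):
        # one marker feature per class avoids the linear-rule class masking
        rng = np.random.default_rng(5)
        X, y = _planted_data(rng, n=240, informative=(0, 1, 2, 3), sep=6.0)
        res = SPLSDA(X, y, n_components=3, keep_x=10).fit()
        assert ber(y, res.predict(X)) < 0.05

    def test_summary_mentions_components(self):
        rng = np.random.default_rng(6)
        X, y = _planted_data(rng, n=60)
        s = SPLSDA(X, y, n_components=2, keep_x=4).fit().summary()
        assert "components" in s and "keepX" in s


class TestTuning:
    def test_separable_ber_near_zero(self):
        rng = np.random.default_rng(7)
        X, y = _planted_data(rng, n=200, informative=(0, 1, 2, 3), sep=6.0)
        tr = tune_splsda(
            X, y, component_grid=(1, 2, 3), keepx_grid=(4, 10),
            n_folds=4, n_repeats=1, seed=0,
        )
        assert tr.best_ber < 0.1

    def test_chance_level_on_permuted_labels(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(400, 20))
        y = np.repeat([2, 3, 4, 5], 100)
        rng.shuffle(y)
        tr = tune_splsda(
            X, y, component_grid=(1,), keepx_grid=(5,),
            n_folds=5, n_repeats=2, seed=1,
        )
        assert tr.best_ber == pytest.approx(0.75, abs=0.05)

    def test_stability_favours_informative_features(self):
        rng = np.random.default_rng(9)
        X, y = _planted_data(rng, n=250, sep=4.0)
        tr = tune_splsda(
            X, y, component_grid=(1,), keepx_grid=(2, 5),
            n_folds=5, n_repeats=2, seed=2,
        )
        stab = tr.stability.max(axis=1)
        informative = max(stab.iloc[0], stab.iloc[1])
        assert informative > stab.iloc[5:].max()

    def test_grouped_folds_respect_subjects(self):
        from discradiomics.splsda import _grouped_folds

        rng = np.random.default_rng(10)
        y = rng.integers(0, 3, 120)
        groups = np.repeat(np.arange(24), 5)
        for tr_idx, va_idx in _grouped_folds(y, groups, 4, 0):
            assert not set(groups[tr_idx]) & set(groups[va_idx])

    def test_ber_balanced_accuracy_identity(self):
        from sklearn.metrics import balanced_accuracy_score

        rng = np.random.default_rng(11)
        y = rng.integers(0, 4, 100)
        pred = rng.integers(0, 4, 100)
        assert ber(y, pred) == pytest.approx(1 - balanced_accuracy_score(y, pred))


class TestSVMBaseline:
    def test_separable_2d(self):
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(0, 0.3, (40, 2)), rng.normal(4, 0.3, (40, 2))])
        y = np.array([0] * 40 + [1] * 40)
        model, grid = svm_baseline(X, y, n_repeats=1, seed=0)
        assert (model.predict(X) == y).all()
        assert grid["balanced_accuracy"].max() > 0.95

    def test_prediction_deterministic(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(60, 2))
        y = rng.integers(0, 2, 60)
        model, _ = svm_baseline(X, y, n_repeats=1, seed=0)
        np.testing.assert_array_equal(model.predict(X), model.predict(X))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            svm_baseline(np.zeros((10, 2)), np.zeros(10))


class TestSerialization:
    def test_json_round_trip_predictions(self):
        rng = np.random.default_rng(14)
        X, y = _planted_data(rng, n=120, informative=(0, 1, 2, 3), sep=4.0)
        res = SPLSDA(X, y, n_components=2, keep_x=5).fit()
        payload = res.to_json()
        from discradiomics.splsda import SPLSDAResults

        Xnew = rng.normal(size=(30, X.shape[1]))
        np.testing.assert_array_equal(
            SPLSDAResults.predict_from_json(payload, Xnew), res.predict(Xnew)
        )
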