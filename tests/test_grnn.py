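import numpy as np
import pytest

from drowse.grnn import (
    GRNNModel,
    classify,
    grnn_predict,
    loo_mse,
    make_windows,
    pairwise_sq_dists,
    windows_to_arrays,
)


def bruteforce_predict(X, y, sigma, q):
    w = np.array([np.exp(-np.sum((q - xi) ** 2) / (2 * sigma**2)) for xi in X])
    return float(w @ y / w.sum())


class TestPredict:
    def test_single_pattern_returns_its_label(self):
        for sigma in (0.01, 1.0, 100.0):
            m = GRNNModel(patterns=[[1.0, 2.0]], labels=[1.0], sigma=sigma)
            assert grnn_predict(m, [50.0, -3.0]) == 1.0

    def test_equidistant_query_averages(self):
        m = GRNNModel(patterns=[[-1.0], [1.0]], labels=[0.0, 1.0], sigma=0.5)
        assert grnn_predict(m, [0.0]) == pytest.approx(0.5)

    def test_matches_bruteforce_oracle(self, rng):
        X = rng.normal(size=(20, 4))
        y = (rng.random(20) > 0.5).astype(float)
        m = GRNNModel(patterns=X, labels=y, sigma=0.8)
        for _ in range(20):
            q = rng.normal(size=4)
            assert grnn_predict(m, q) == pytest.approx(
                bruteforce_predict(X, y, 0.8, q), abs=1e-12
            )

    def test_prediction_is_convex_combination(self, rng):
        X = rng.normal(size=(30, 3))
        y = (rng.random(30) > 0.3).astype(float)
        m = GRNNModel(patterns=X, labels=y, sigma=0.3)
        preds = grnn_predict(m, rng.normal(size=(50, 3)) * 3)
        assert np.all(preds >= y.min()) and np.all(preds <= y.max())

    def test_large_sigma_limit_is_label_mean(self, rng):
        X = rng.normal(size=(25, 2))
        y = (rng.random(25) > 0.4).astype(float)
        m = GRNNModel(patterns=X, labels=y, sigma=1e6)
        assert grnn_predict(m, [0.3, -0.7]) == pytest.approx(y.mean(), abs=1e-6)

    def test_permutation_invariance(self, rng):
        X = rng.normal(size=(15, 3))
        y = (rng.random(15) > 0.5).astype(float)
        perm = rng.permutation(15)
        a = GRNNModel(patterns=X, labels=y, sigma=0.5)
        b = GRNNModel(patterns=X[perm], labels=y[perm], sigma=0.5)
        q = rng.normal(size=3)
        assert grnn_predict(a, q) == pytest.approx(grnn_predict(b, q), abs=1e-12)

    def test_underflow_falls_back_to_nearest(self):
        m = GRNNModel(patterns=[[0.0], [100.0]], labels=[0.0, 1.0], sigma=1e-3)
        assert grnn_predict(m, [70.0]) == 1.0

    def test_dimension_mismatch_rejected(self):
        m = GRNNModel(patterns=[[0.0, 1.0]], labels=[1.0], sigma=1.0)
        with pytest.raises(ValueError):
            grnn_predict(m, [0.0, 1.0, 2.0])

    def test_model_validation(self):
        with pytest.raises(ValueError):
            GRNNModel(patterns=[[0.0]], labels=[0.5], sigma=1.0)
        with pytest.raises(ValueError):
            GRNNModel(patterns=[[0.0]], labels=[0.0], sigma=0.0)

    def test_json_round_trip(self, rng, tmp_path):
        m = GRNNModel(
            patterns=rng.normal(size=(5, 2)),
            labels=(rng.random(5) > 0.5).astype(float),
            sigma=0.42,
        )
        path = tmp_path / "grnn.json"
        m.to_json(path)
        back = GRNNModel.from_json(path)
        q = rng.normal(size=2)
        assert grnn_predict(back, q) == pytest.approx(grnn_predict(m, q), abs=1e-12)


class TestClassify:
    def test_threshold_and_boundary(self):
        m = GRNNModel(patterns=[[-1.0], [1.0]], labels=[0.0, 1.0], sigma=0.5)
        assert classify(m, [10.0]) == "fatigue"
        assert classify(m, [-10.0]) == "non_fatigue"
        assert classify(m, [0.0]) == "fatigue"  # score 0.5, boundary inclusive

    def test_all_negative_model_never_flags(self, rng):
        m = GRNNModel(patterns=rng.normal(size=(10, 2)), labels=np.zeros(10), sigma=0.5)
        assert classify(m, [5.0, 5.0]) == "non_fatigue"


class TestLooMse:
    def test_coincident_agreeing_patterns(self):
        assert loo_mse([[1.0], [1.0]], [1.0, 1.0], sigma=0.5) == 0.0

    def test_separated_opposite_labels_at_small_sigma(self):
        # each left-out sample is predicted as the other's label
        assert loo_mse([[0.0], [10.0]], [0.0, 1.0], sigma=0.05) == pytest.approx(1.0)

    def test_matches_per_sample_exclusion_oracle(self, rng):
        X = rng.normal(size=(15, 3))
        y = (rng.random(15) > 0.5).astype(float)
        sigma = 0.7
        errs = []
        for i in range(15):
            keep = np.ones(15, bool)
            keep[i] = False
            errs.append(
                (bruteforce_predict(X[keep], y[keep], sigma, X[i]) - y[i]) ** 2
            )
        assert loo_mse(X, y, sigma) == pytest.approx(float(np.mean(errs)), abs=1e-12)

    def test_cached_distances_equivalent(self, rng):
        X = rng.normal(size=(12, 2))
        y = (rng.random(12) > 0.5).astype(float)
        d2 = pairwise_sq_dists(X)
        assert loo_mse(X, y, 0.3, d2=d2) == loo_mse(X, y, 0.3)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            loo_mse([[0.0]], [1.0], sigma=0.5)


class TestParameterRecovery:
    def test_separated_gaussian_classes_classified(self, rng):
        """Two 6-D Gaussian classes 4 sd apart: LOO-tuned GRNN >= 95% held out."""
        d, n = 6, 200
        mu = np.zeros(d)
        mu2 = np.full(d, 4.0 / np.sqrt(d))  # centres 4 sd apart overall
        Xtr = np.vstack([rng.normal(mu, 1, (n, d)), rng.normal(mu2, 1, (n, d))])
        ytr = np.repeat([0.0, 1.0], n)
        d2 = pairwise_sq_dists(Xtr)
        grid = np.geomspace(0.05, 2.0, 60)
        sigma = grid[np.argmin([loo_mse(Xtr, ytr, s, d2=d2) for s in grid])]
        m = GRNNModel(patterns=Xtr, labels=ytr, sigma=float(sigma))
        Xte = np.vstack([rng.normal(mu, 1, (n, d)), rng.normal(mu2, 1, (n, d))])
        yte = np.repeat([0, 1], n)
        pred = (grnn_predict(m, Xte) >= 0.5).astype(int)
        assert np.mean(pred == yte) >= 0.95


class TestMakeWindows:
    def test_window_counts(self, rng):
        X = rng.normal(size=(900, 3))
        y = np.zeros(900)
        assert len(make_windows(X, y, 900, 80)) == 1
        X = rng.normal(size=(980, 3))
        assert len(make_windows(X, np.zeros(980), 900, 80)) == 2

    def test_constant_labels_propagate(self, rng):
        samples = make_windows(rng.normal(size=(500, 2)), np.ones(500), 100, 50)
        assert all(s.label == 1 for s in samples)

    def test_majority_and_tie_rule(self):
        X = np.zeros((4, 1))
        assert make_windows(X, [1, 1, 1, 0], 4, 1)[0].label == 1
        assert make_windows(X, [0, 0, 0, 1], 4, 1)[0].label == 0
        assert make_windows(X, [0, 1, 0, 1], 4, 1)[0].label == 1  # tie -> fatigue

    def test_features_are_column_means(self, rng):
        X = rng.normal(size=(10, 3))
        s = make_windows(X, np.zeros(10), 10, 5)[0]
        assert np.allclose(s.features, X.mean(axis=0))

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ValueError):
            make_windows(rng.normal(size=(10, 2)), np.zeros(10), 11, 1)

    def test_arrays_round_trip(self, rng):
        samples = make_windows(rng.normal(size=(300, 2)), np.ones(300), 100, 100)
        X, y = windows_to_arrays(samples)
        assert X.shape == (3, 2) and np.all(y == 1.0)
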