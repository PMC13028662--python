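"""KNN regression: metrics, weighting, normalization, splitting, evaluation."""

import numpy as np
import pytest
from sklearn.neighbors import KNeighborsRegressor
from sklearn.preprocessing import MinMaxScaler

from maeopt.datasets import FCRC
from maeopt.knn import (
    METRICS,
    WEIGHTINGS,
    KNNRegressor,
    SymmetricMinMaxScaler,
    evaluate,
    fit_normalizer,
    pairwise_distances,
    split_train_val,
)


def _metric_state(X, metric):
    kw = {}
    if metric == "mahalanobis":
        kw["mahalanobis_vi"] = np.linalg.inv(np.cov(X, rowvar=False) + 1e-8 * np.eye(X.shape[1]))
    elif metric == "seuclidean":
        kw["seuclidean_var"] = X.var(axis=0, ddof=1)
    return kw


class TestDistances:
    @pytest.mark.parametrize(
        "metric,u,v,expected",
        [
            ("euclidean", (0, 0), (3, 4), 5.0),
            ("cityblock", (0, 0), (3, 4), 7.0),
            ("chebyshev", (0, 0), (3, 4), 4.0),
            ("minkowski", (0, 0), (1, 1), 2 ** (1 / 3)),
            ("hamming", (1, 2, 3, 4), (1, 2, 0, 0), 0.5),
            ("jaccard", (1, 0, 2, 0), (1, 0, 3, 4), 2 / 3),
            ("cosine", (1, 0), (0, 1), 1.0),
        ],
    )
    def test_hand_computed_values(self, metric, u, v, expected):
        D = pairwise_distances(
            np.array([u], float), np.array([v], float), metric, minkowski_exponent=3.0
        )
        assert D[0, 0] == pytest.approx(expected)

    @pytest.mark.parametrize("metric", METRICS)
    def test_identity_and_symmetry(self, metric, rng):
        U = rng.normal(size=(1000, 5))
        kw = _metric_state(U, metric)
        D = pairwise_distances(U[:200], U[:200], metric, **kw)
        assert np.all(np.abs(np.diag(D)) < 1e-10)
        np.testing.assert_allclose(D, D.T, atol=1e-10)
        assert np.all(D >= 0)

    def test_degenerate_vectors_give_unit_distance(self):
        const = np.array([[2.0, 2.0, 2.0]])
        zero = np.zeros((1, 3))
        other = np.array([[1.0, 2.0, 3.0]])
        assert pairwise_distances(const, other, "correlation")[0, 0] == 1.0
        assert pairwise_distances(const, other, "spearman")[0, 0] == 1.0
        assert pairwise_distances(zero, other, "cosine")[0, 0] == 1.0

    def test_spearman_is_rank_correlation_distance(self, rng):
        from scipy.stats import spearmanr

        u, v = rng.normal(size=(2, 10))
        d = pairwise_distances(u[None], v[None], "spearman")[0, 0]
        assert d == pytest.approx(1 - spearmanr(u, v).statistic)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown metric"):
            pairwise_distances(np.zeros((1, 2)), np.zeros((1, 2)), "manhattan")


class TestNormalizer:
    def test_maps_to_unit_interval_endpoints(self, rng):
        X = rng.uniform(10, 50, size=(20, 3))
        scaler = fit_normalizer(X)
        Z = scaler.transform(X)
        np.testing.assert_allclose(Z.min(axis=0), -1.0)
        np.testing.assert_allclose(Z.max(axis=0), 1.0)
        mid = 0.5 * (X.min(axis=0) + X.max(axis=0))
        np.testing.assert_allclose(scaler.transform(mid[None, :]), 0.0, atol=1e-12)

    def test_matches_sklearn_minmax(self, rng):
        X = rng.normal(size=(30, 4))
        ours = fit_normalizer(X).transform(X)
        ref = MinMaxScaler(feature_range=(-1, 1)).fit_transform(X)
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_round_trip(self, rng):
        X = rng.normal(size=(15, 2))
        scaler = fit_normalizer(X)
        np.testing.assert_allclose(
            scaler.inverse_transform(scaler.transform(X)), X, atol=1e-12
        )

    def test_constant_feature_rejected(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.raises(ValueError, match="constant feature"):
            fit_normalizer(X)


class TestKNNPredict:
    def test_zero_distance_returns_training_target(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        y = np.array([5.0, 7.0, 9.0])
        for weighting in WEIGHTINGS:
            model = KNNRegressor(n_neighbors=1, weighting=weighting).fit(X, y)
            np.testing.assert_allclose(model.predict(X), y)

    def test_equal_weight_mean(self):
        X = np.array([[0.0], [1.0], [10.0]])
        y = np.array([10.0, 40.0, 1000.0])
        model = KNNRegressor(n_neighbors=2, weighting="equal").fit(X, y)
        assert model.predict(np.array([[0.4]]))[0] == pytest.approx(25.0)

    def test_squared_inverse_weighting_arithmetic(self):
        # distances 1 and 2 to targets 10 and 40: (10*1 + 40*0.25)/1.25 = 16
        X = np.array([[1.0], [2.0], [10.0]])
        y = np.array([10.0, 40.0, 1000.0])
        model = KNNRegressor(n_neighbors=2, weighting="squared_inverse").fit(X, y)
        assert model.predict(np.array([[0.0]]))[0] == pytest.approx(16.0)

    def test_k_equals_n_equal_weights_is_global_mean(self, rng):
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        model = KNNRegressor(n_neighbors=12, weighting="equal").fit(X, y)
        q = rng.normal(size=(4, 3))
        np.testing.assert_allclose(model.predict(q), y.mean(), atol=1e-12)

    def test_matches_sklearn_reference(self, rng):
        """Independent cross-check against scikit-learn's KNN regressor."""
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        q = rng.normal(size=(10, 4))
        ours = KNNRegressor(n_neighbors=5, metric="euclidean", weighting="equal")
        ref = KNeighborsRegressor(n_neighbors=5, weights="uniform")
        np.testing.assert_allclose(
            ours.fit(X, y).predict(q), ref.fit(X, y).predict(q), atol=1e-10
        )
        ours_w = KNNRegressor(n_neighbors=5, metric="euclidean", weighting="inverse")
        ref_w = KNeighborsRegressor(n_neighbors=5, weights="distance")
        np.testing.assert_allclose(
            ours_w.fit(X, y).predict(q), ref_w.fit(X, y).predict(q), atol=1e-10
        )

    def test_row_order_invariance(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        q = rng.normal(size=(5, 3))
        model = KNNRegressor(n_neighbors=4, weighting="inverse").fit(X, y)
        perm = rng.permutation(20)
        model_p = KNNRegressor(n_neighbors=4, weighting="inverse").fit(X[perm], y[perm])
        np.testing.assert_allclose(model.predict(q), model_p.predict(q), atol=1e-10)

    def test_k_larger_than_training_rejected(self):
        X = np.zeros((3, 2))
        y = np.zeros(3)
        with pytest.raises(ValueError, match="n_neighbors"):
            KNNRegressor(n_neighbors=4).fit(X, y)

    @pytest.mark.parametrize("metric", METRICS)
    @pytest.mark.parametrize("weighting", WEIGHTINGS)
    def test_finite_predictions_on_study_data(self, study, metric, weighting):
        """Every metric/weighting/k<=5 configuration stays NaN-free on the
        27-run experiment."""
        Z = fit_normalizer(study.actual_matrix()).transform(study.actual_matrix())
        y = study.response_means(FCRC)
        for k in (1, 3, 5):
            model = KNNRegressor(n_neighbors=k, metric=metric, weighting=weighting)
            pred = model.fit(Z, y).predict(Z)
            assert np.all(np.isfinite(pred))


class TestSplit:
    def test_sizes_and_partition(self):
        train, val = split_train_val(27, 0.7, seed=3)
        assert len(train) == 19 and len(val) == 8
        assert set(train) | set(val) == set(range(27))
        assert set(train) & set(val) == set()

    def test_seed_determinism(self):
        assert np.array_equal(split_train_val(27, 0.7, 5)[0], split_train_val(27, 0.7, 5)[0])
        assert not np.array_equal(split_train_val(27, 0.7, 5)[0], split_train_val(27, 0.7, 6)[0])

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            split_train_val(10, 1.0)


class TestEvaluate:
    def test_perfect_predictions(self):
        X = np.arange(10.0)[:, None]
        y = 2 * np.arange(10.0)
        model = KNNRegressor(n_neighbors=1).fit(X, y)
        m = evaluate(model, X, y)
        assert m.r == pytest.approx(1.0)
        assert m.rmse == pytest.approx(0.0)

    def test_constant_shift(self):
        X = np.arange(10.0)[:, None]
        y = 2 * np.arange(10.0)
        model = KNNRegressor(n_neighbors=1).fit(X, y)
        m = evaluate(model, X, y + 3.0)
        assert m.rmse == pytest.approx(3.0)
        assert m.r == pytest.approx(1.0)

    def test_training_r_near_one_under_distance_weighting(self, study):
        """The zero-distance rule makes training-set evaluation exact at
        every unreplicated design point; at the three replicated center
        runs the prediction is the replicate-group mean, so the training
        correlation is near-perfect (~0.9999) rather than exactly 1."""
        Z = fit_normalizer(study.actual_matrix()).transform(study.actual_matrix())
        y = study.response_means(FCRC)
        center = np.all(Z == 0.0, axis=1)
        for k in (1, 2, 5):
            model = KNNRegressor(n_neighbors=k, weighting="inverse").fit(Z, y)
            pred = model.predict(Z)
            np.testing.assert_allclose(pred[~center], y[~center], atol=1e-12)
            m = evaluate(model, Z, y)
            assert m.r > 0.999

    def test_constant_predictions_report_missing_r(self):
        X = np.arange(4.0)[:, None]
        y = np.ones(4)
        model = KNNRegressor(n_neighbors=4, weighting="equal").fit(X, y)
        m = evaluate(model, X + 100.0, np.arange(4.0))
        assert m.r is None
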