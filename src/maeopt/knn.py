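"""K-nearest-neighbors regression with configurable metrics and weighting.

The regressor is deliberately brute-force (the datasets it targets are
designed experiments of a few dozen runs) and supports the eleven distance
metrics and three distance-weighting schemes used for surrogate modeling
of extraction responses: equal weights, inverse distance (1/d), and
squared inverse distance (1/d^2).  Inputs are normalized to [-1, +1] per
feature before any distance computation.

Metric conventions on real-valued vectors:

* ``jaccard``: fraction of coordinates that differ among those where at
  least one vector is nonzero (0/0 -> 0).
* ``hamming``: fraction of coordinates with exact inequality.
* ``cosine``/``correlation``/``spearman``: one minus the respective
  similarity; undefined cases (zero or constant vectors) give distance 1.
* ``mahalanobis``/``seuclidean``: statistics come from the training inputs
  only, with a 1e-8 diagonal ridge when the covariance is near-singular.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "METRICS",
    "WEIGHTINGS",
    "SymmetricMinMaxScaler",
    "KNNRegressor",
    "EvalMetrics",
    "fit_normalizer",
    "pairwise_distances",
    "split_train_val",
    "evaluate",
]

METRICS = (
    "euclidean",
    "chebyshev",
    "minkowski",
    "mahalanobis",
    "cosine",
    "correlation",
    "spearman",
    "hamming",
    "jaccard",
    "cityblock",
    "seuclidean",
)
WEIGHTINGS = ("equal", "inverse", "squared_inverse")

#: Metrics whose similarity form is undefined on degenerate vectors; the
#: resulting NaN distances are mapped to 1.
_NAN_TO_ONE = {"cosine", "correlation", "spearman"}


class SymmetricMinMaxScaler(TransformerMixin, BaseEstimator):
    """Per-feature linear map onto [-1, +1]: x' = 2(x - min)/(max - min) - 1."""

    def fit(self, X, y=None):
        X = check_array(X)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        if np.any(self.data_max_ <= self.data_min_):
            bad = np.nonzero(self.data_max_ <= self.data_min_)[0]
            raise ValueError(f"constant feature(s) {bad.tolist()}: normalization degenerate")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "data_min_")
        X = check_array(X)
        return 2.0 * (X - self.data_min_) / (self.data_max_ - self.data_min_) - 1.0

    def inverse_transform(self, X):
        check_is_fitted(self, "data_min_")
        X = check_array(X)
        return self.data_min_ + 0.5 * (X + 1.0) * (self.data_max_ - self.data_min_)


def fit_normalizer(inputs: np.ndarray) -> SymmetricMinMaxScaler:
    """Fit the [-1, +1] normalizer on a feature table."""
    return SymmetricMinMaxScaler().fit(inputs)


def _regularized_cov(X: np.ndarray) -> np.ndarray:
    cov = np.atleast_2d(np.cov(X, rowvar=False))
    if np.linalg.cond(cov) > 1e12 or not np.isfinite(np.linalg.cond(cov)):
        cov = cov + 1e-8 * np.eye(cov.shape[0])
    return cov

def pairwise_distances(
    U: np.ndarray,
    V: np.ndarray,
    metric: str,
    minkowski_exponent: float = 2.0,
    mahalanobis_vi: np.ndarray | None = None,
    seuclidean_var: np.ndarray | None = None,
) -> np.ndarray:
    """Distance matrix between the rows of U and V under one of the 11 metrics.

    ``mahalanobis_vi`` (inverse covariance) and ``seuclidean_var`` (per-
    feature variances) must be supplied for their metrics — they are
    training-set statistics, not derived from U/V here.
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if metric == "minkowski":
        if minkowski_exponent <= 0:
            raise ValueError("minkowski exponent must be positive")
        D = cdist(U, V, "minkowski", p=minkowski_exponent)
    elif metric == "mahalanobis":
        if mahalanobis_vi is None:
            raise ValueError("mahalanobis requires the training inverse covariance")
        D = cdist(U, V, "mahalanobis", VI=mahalanobis_vi)
    elif metric == "seuclidean":
        if seuclidean_var is None:
            raise ValueError("seuclidean requires the training per-feature variances")
        D = cdist(U, V, "seuclidean", V=seuclidean_var)
    elif metric == "spearman":
        # rank each vector across its coordinates (average ranks on ties),
        # then one minus the Pearson correlation of the rank vectors
        RU = rankdata(U, axis=1)
        RV = rankdata(V, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            D = cdist(RU, RV, "correlation")
    elif metric in ("cosine", "correlation"):
        with np.errstate(invalid="ignore", divide="ignore"):
            D = cdist(U, V, metric)
    elif metric == "jaccard":
        # value-inequality convention: #(u_i != v_i) over #(u_i != 0 or
        # v_i != 0); 0/0 -> 0.  (scipy's jaccard instead compares
        # presence/absence, a different quantity on real vectors.)
        diff = (U[:, None, :] != V[None, :, :]).sum(axis=2).astype(float)
        union = ((U[:, None, :] != 0) | (V[None, :, :] != 0)).sum(axis=2)
        with np.errstate(invalid="ignore"):
            D = np.where(union > 0, diff / np.maximum(union, 1), 0.0)
    elif metric in ("euclidean", "chebyshev", "hamming", "cityblock"):
        D = cdist(U, V, metric)
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if metric in _NAN_TO_ONE:
        D = np.where(np.isnan(D), 1.0, D)
    # clip the tiny negative values cosine/correlation can produce
    return np.maximum(D, 0.0)


class KNNRegressor(RegressorMixin, BaseEstimator):
    """Brute-force KNN regression over normalized inputs.

    Parameters
    ----------
    n_neighbors : int
        Neighbor count k (must not exceed the training-set size).
    metric : str
        One of :data:`METRICS`.
    weighting : str
        ``"equal"`` (plain mean), ``"inverse"`` (weights 1/d) or
        ``"squared_inverse"`` (weights 1/d^2).  If any selected neighbor is
        at distance zero, the prediction is the unweighted mean of the
        zero-distance targets.
    minkowski_exponent : float
        Order of the Minkowski metric (used only when metric="minkowski").

    Neighbor ties at the k-th position break by ascending training index
    (stable sort on distance).
    """

    def __init__(
        self,
        n_neighbors: int = 3,
        metric: str = "euclidean",
        weighting: str = "equal",
        minkowski_exponent: float = 2.0,
    ):
        self.n_neighbors = n_neighbors
        self.metric = metric
        self.weighting = weighting
        self.minkowski_exponent = minkowski_exponent

    def fit(self, X, y):
        X = check_array(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; choose from {METRICS}")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(
                f"unknown weighting {self.weighting!r}; choose from {WEIGHTINGS}"
            )
        if not 1 <= self.n_neighbors <= X.shape[0]:
            raise ValueError(
                f"n_neighbors={self.n_neighbors} must be in [1, {X.shape[0]}]"
            )
        self.X_train_ = X.copy()
        self.y_train_ = y.copy()
        self.n_features_in_ = X.shape[1]
        self.mahalanobis_vi_ = None
        self.seuclidean_var_ = None
        if self.metric == "mahalanobis":
            self.mahalanobis_vi_ = np.linalg.inv(_regularized_cov(X))
        elif self.metric == "seuclidean":
            var = X.var(axis=0, ddof=1)
            self.seuclidean_var_ = np.where(var <= 1e-12, 1e-8, var)
        return self

    def _distances(self, X) -> np.ndarray:
        return pairwise_distances(
            X,
            self.X_train_,
            self.metric,
            minkowski_exponent=self.minkowski_exponent,
            mahalanobis_vi=self.mahalanobis_vi_,
            seuclidean_var=self.seuclidean_var_,
        )

    def predict(self, X):
        check_is_fitted(self, "X_train_")
        X = check_array(X)
        D = self._distances(X)
        k = self.n_neighbors
        out = np.empty(X.shape[0])
        for row, d in enumerate(D):
            idx = np.argsort(d, kind="stable")[:k]
            dk = d[idx]
            yk = self.y_train_[idx]
            if np.any(dk == 0.0):
                out[row] = yk[dk == 0.0].mean()
            elif self.weighting == "equal":
                out[row] = yk.mean()
            else:
                power = 1.0 if self.weighting == "inverse" else 2.0
                w = 1.0 / dk**power
                out[row] = float(np.average(yk, weights=w))
        return out


@dataclass(frozen=True)
class EvalMetrics:
    """Correlation (Pearson R of predicted vs observed) and RMSE of a model."""

    r: float | None
    rmse: float


def split_train_val(
    n: int, fraction: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random train/validation index partition.

    The training part has ceil(fraction * n) members; the two parts are
    disjoint and exhaustive.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = ceil(fraction * n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def evaluate(model: KNNRegressor, X, y) -> EvalMetrics:
    """Pearson R and RMSE of model predictions against observations.

    R is None (undefined) when predictions or observations are constant.
    RMSE uses the evaluated set size as divisor.
    """
    y = np.asarray(y, dtype=float).ravel()
    pred = model.predict(X)
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    if len(y) < 2 or np.std(pred) == 0.0 or np.std(y) == 0.0:
        r = None
    else:
        r = float(np.corrcoef(pred, y)[0, 1])
    return EvalMetrics(r=r, rmse=rmse)
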