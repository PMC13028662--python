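"""Second-order response-surface modeling on coded factors.

The canonical model is the full quadratic polynomial

    y = b0 + sum_j bj xj + sum_{i<j} bij xi xj + sum_j bjj xj^2 + e

fitted by ordinary least squares to the per-run response means of a
Box-Behnken experiment.  For k factors the model has
p = 1 + 2k + k(k-1)/2 terms (15 for k = 4).  Replicated design points
(the center runs of a BBD) allow the residual sum of squares to be
partitioned into pure error and lack of fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .design import BBDDataset

__all__ = [
    "QuadraticSurfaceRegressor",
    "AnovaReport",
    "quadratic_terms",
    "expand_quadratic",
    "fit_quadratic",
    "anova",
    "response_correlation",
    "cube_vertex_predictions",
    "prediction_grid",
]


def quadratic_terms(k: int) -> list[str]:
    """Canonical term names: intercept, linear, interactions (i<j), quadratic."""
    names = ["Intercept"] + [f"x{j + 1}" for j in range(k)]
    names += [f"x{i + 1}:x{j + 1}" for i, j in combinations(range(k), 2)]
    names += [f"x{j + 1}^2" for j in range(k)]
    return names


def expand_quadratic(X: np.ndarray) -> np.ndarray:
    """Design-matrix expansion of coded factors into the full quadratic basis."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    cols = [np.ones(n)]
    cols.extend(X[:, j] for j in range(k))
    cols.extend(X[:, i] * X[:, j] for i, j in combinations(range(k), 2))
    cols.extend(X[:, j] ** 2 for j in range(k))
    return np.column_stack(cols)


@dataclass(frozen=True)
class AnovaReport:
    """Goodness-of-fit summary of a quadratic response-surface fit.

    ``lof_f``/``lof_p`` are None when the design has fewer than two
    replicated runs (no pure-error estimate).
    """

    r2: float
    r2_adj: float
    rmse: float
    model_f: float
    model_p: float
    lof_f: float | None
    lof_p: float | None
    coef_p: pd.Series

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "R2": self.r2,
            "R2_adj": self.r2_adj,
            "RMSE": self.rmse,
            "model_F": self.model_f,
            "model_p": self.model_p,
            "lack_of_fit_F": self.lof_f,
            "lack_of_fit_p": self.lof_p,
        }
        return pd.DataFrame({"value": rows})


class QuadraticSurfaceRegressor(RegressorMixin, BaseEstimator):
    """Full second-order polynomial response surface fitted by OLS.

    Parameters
    ----------
    response_name : str, optional
        Label carried through reports.

    Attributes
    ----------
    intercept_ : float
    coef_lin_ : ndarray of shape (k,)
        Linear coefficients, one per factor.
    coef_int_ : dict[(int, int), float]
        Interaction coefficients keyed by factor-index pair (i < j).
    coef_quad_ : ndarray of shape (k,)
        Pure quadratic coefficients.
    coef_ : ndarray of shape (p,)
        All coefficients in canonical term order.
    se_, tvalues_, pvalues_ : ndarray of shape (p,)
        Standard errors and two-sided t tests with ``residual_df_`` degrees
        of freedom.
    sse_, sst_, residual_df_ : residual and total sums of squares, residual df.
    """

    def __init__(self, response_name: str = "y"):
        self.response_name = response_name

    def fit(self, X, y):
        X = check_array(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        n, k = X.shape
        D = expand_quadratic(X)
        p = D.shape[1]
        if n <= p:
            raise ValueError(
                f"need more runs ({n}) than model terms ({p}) for a residual"
            )
        if np.linalg.matrix_rank(D) < p:
            raise ValueError("design matrix is rank deficient; model not estimable")

        res = sm.OLS(y, D).fit()
        self.n_features_in_ = k
        self.term_names_ = quadratic_terms(k)
        self.coef_ = res.params.copy()
        self.se_ = res.bse.copy()
        self.tvalues_ = res.tvalues.copy()
        self.pvalues_ = res.pvalues.copy()
        self.intercept_ = float(self.coef_[0])
        self.coef_lin_ = self.coef_[1 : 1 + k].copy()
        pairs = list(combinations(range(k), 2))
        self.coef_int_ = {
            pair: float(c) for pair, c in zip(pairs, self.coef_[1 + k : 1 + k + len(pairs)])
        }
        self.coef_quad_ = self.coef_[1 + k + len(pairs) :].copy()
        self.residual_df_ = int(res.df_resid)
        self.sse_ = float(res.ssr)
        self.sst_ = float(res.centered_tss)
        self.X_fit_ = X.copy()
        self.y_fit_ = y.copy()
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return expand_quadratic(X) @ self.coef_

    def coefficients(self) -> pd.DataFrame:
        """Coefficient table (estimate, se, t, p) indexed by term name."""
        check_is_fitted(self, "coef_")
        return pd.DataFrame(
            {
                "estimate": self.coef_,
                "se": self.se_,
                "t": self.tvalues_,
                "p_value": self.pvalues_,
            },
            index=pd.Index(self.term_names_, name="term"),
        )

    def anova(self, pure_error_groups: np.ndarray | None = None) -> AnovaReport:
        """ANOVA summary; see module-level :func:`anova` for the BBD wrapper.

        ``pure_error_groups`` assigns each training run to a replicate group
        (None = derive groups from identical rows of the training design).
        Lack of fit is reported only when some group has >= 2 members.
        """
        check_is_fitted(self, "coef_")
        n = len(self.y_fit_)
        p = len(self.coef_)
        df_res = self.residual_df_
        r2 = 1.0 - self.sse_ / self.sst_
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
        rmse = float(np.sqrt(self.sse_ / df_res))
        ssr = self.sst_ - self.sse_
        model_f = (ssr / (p - 1)) / (self.sse_ / df_res)
        model_p = float(stats.f.sf(model_f, p - 1, df_res))

        if pure_error_groups is None:
            _, pure_error_groups = np.unique(self.X_fit_, axis=0, return_inverse=True)
        ss_pe = 0.0
        df_pe = 0
        for g in np.unique(pure_error_groups):
            yg = self.y_fit_[pure_error_groups == g]
            if len(yg) >= 2:
                ss_pe += float(((yg - yg.mean()) ** 2).sum())
                df_pe += len(yg) - 1
        lof_f = lof_p = None
        if df_pe >= 1 and df_res > df_pe and ss_pe > 0:
            ss_lof = self.sse_ - ss_pe
            df_lof = df_res - df_pe
            lof_f = (ss_lof / df_lof) / (ss_pe / df_pe)
            lof_p = float(stats.f.sf(lof_f, df_lof, df_pe))

        coef_p = pd.Series(self.pvalues_, index=self.term_names_)
        return AnovaReport(r2, r2_adj, rmse, float(model_f), model_p, lof_f, lof_p, coef_p)


def fit_quadratic(dataset: BBDDataset, response_name: str) -> QuadraticSurfaceRegressor:
    """OLS fit of the full quadratic model to one response's run means."""
    model = QuadraticSurfaceRegressor(response_name=response_name)
    return model.fit(dataset.coded_matrix(), dataset.response_means(response_name))


def anova(fit: QuadraticSurfaceRegressor, dataset: BBDDataset) -> AnovaReport:
    """ANOVA report with pure error taken from the dataset's replicated runs."""
    coded = dataset.coded_matrix()
    _, groups = np.unique(coded, axis=0, return_inverse=True)
    return fit.anova(pure_error_groups=groups)


def response_correlation(dataset: BBDDataset, resp_a: str, resp_b: str) -> float:
    """Pearson correlation of two responses' observed run means."""
    a = dataset.response_means(resp_a)
    b = dataset.response_means(resp_b)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined: a response has zero variance")
    return float(stats.pearsonr(a, b).statistic)


def cube_vertex_predictions(fit: QuadraticSurfaceRegressor) -> dict[tuple[float, ...], float]:
    """Model predictions at all 2^k coded (+/-1) vertices of the factor cube."""
    check_is_fitted(fit, "coef_")
    k = fit.n_features_in_
    vertices = np.array(list(product((-1.0, 1.0), repeat=k)))
    preds = fit.predict(vertices)
    return {tuple(v): float(p) for v, p in zip(vertices, preds)}


def prediction_grid(
    fit: QuadraticSurfaceRegressor,
    axis_i: int,
    axis_j: int,
    fixed: np.ndarray | None = None,
    resolution: int = 25,
) -> pd.DataFrame:
    """Regular coded-space prediction grid over two factor axes.

    The remaining coordinates are held at ``fixed`` (default: all-center).
    Returns a tidy frame with columns ``xi``, ``xj``, ``prediction`` —
    numeric export for external contour/profiler plotting.
    """
    check_is_fitted(fit, "coef_")
    k = fit.n_features_in_
    if axis_i == axis_j:
        raise ValueError("grid axes must be distinct")
    if fixed is None:
        fixed = np.zeros(k)
    fixed = np.asarray(fixed, dtype=float)
    axis = np.linspace(-1.0, 1.0, resolution)
    rows = []
    for xi, xj in product(axis, axis):
        point = fixed.copy()
        point[axis_i] = xi
        point[axis_j] = xj
        rows.append((xi, xj, float(fit.predict(point[None, :])[0])))
    return pd.DataFrame(rows, columns=["xi", "xj", "prediction"])
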