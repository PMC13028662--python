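"""End-to-end optimization stages.

Stages composed here:

1. **Surrogate tuning** — a dragonfly search over the mixed KNN
   hyperparameter space (metric x weighting x neighbor count x Minkowski
   exponent), minimizing validation RMSE on a seeded 70/30 split.
2. **Desirability optimization of the response surface** — Derringer
   maximize-type desirabilities combined by geometric mean and maximized
   over the coded factor box (dense grid plus local refinement).
3. **Multi-objective surrogate optimization** — MODA over KNN surrogates
   trained on the full dataset, with the compromise point chosen as the
   archive member maximizing the summed predicted responses.
4. **Validation reporting** — absolute errors between experimental and
   predicted responses at the chosen optimum, with a summed-response row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize as sp_optimize
from sklearn.base import BaseEstimator

from .design import BBDDataset
from .dragonfly import DAConfig, ParetoArchive, da_minimize, moda_optimize
from .knn import (
    METRICS,
    WEIGHTINGS,
    EvalMetrics,
    KNNRegressor,
    evaluate,
    fit_normalizer,
    split_train_val,
)
from .rsm import QuadraticSurfaceRegressor

__all__ = [
    "DesirabilitySpec",
    "TuningResult",
    "DragonflyKNNTuner",
    "tune_knn",
    "desirability",
    "overall_desirability",
    "optimize_rsm",
    "optimize_knn_moda",
    "validation_report",
]

#: Baseline configuration injected into the tuner's initial swarm, so the
#: search can never return something worse than a sane default.
DEFAULT_KNN_PARAMS = {"metric": "euclidean", "weighting": "equal", "n_neighbors": 3}


# ---------------------------------------------------------------------------
# Desirability

@dataclass(frozen=True)
class DesirabilitySpec:
    """Maximize-type desirability anchors for one response.

    d(y) = 0 below ``lower``, 1 above ``target``, and
    ((y - lower)/(target - lower))^shape in between.
    """

    lower: float
    target: float
    shape: float = 1.0

    def __post_init__(self) -> None:
        if not self.lower < self.target:
            raise ValueError("desirability needs lower < target")
        if self.shape <= 0:
            raise ValueError("shape exponent must be positive")


def desirability(value: float, spec: DesirabilitySpec) -> float:
    """Per-response desirability in [0, 1]."""
    if value <= spec.lower:
        return 0.0
    if value >= spec.target:
        return 1.0
    return float(((value - spec.lower) / (spec.target - spec.lower)) ** spec.shape)


def overall_desirability(values: Mapping[str, float], specs: Mapping[str, DesirabilitySpec]) -> float:
    """Geometric mean of the per-response desirabilities."""
    ds = [desirability(values[name], specs[name]) for name in specs]
    return float(np.prod(ds) ** (1.0 / len(ds)))


# ---------------------------------------------------------------------------
# KNN hyperparameter tuning

@dataclass
class TuningResult:
    """Outcome of a surrogate-tuning run."""

    best_params: dict
    metrics: dict[str, EvalMetrics]
    evaluation_log: list[tuple[dict, float]] = field(default_factory=list)

    @property
    def best_validation_rmse(self) -> float:
        return self.metrics["validation"].rmse


def _decode_candidate(z: np.ndarray, n_train: int) -> dict:
    """Round a continuous search vector to an admissible hyperparameter set."""
    metric = METRICS[int(np.clip(round(z[0]), 0, len(METRICS) - 1))]
    weighting = WEIGHTINGS[int(np.clip(round(z[1]), 0, len(WEIGHTINGS) - 1))]
    k = int(np.clip(round(z[2]), 1, n_train))
    params = {"metric": metric, "weighting": weighting, "n_neighbors": k}
    if metric == "minkowski":
        params["minkowski_exponent"] = float(np.clip(z[3], 1.0, 10.0))
    return params


class DragonflyKNNTuner(BaseEstimator):
    """Dragonfly-driven hyperparameter search for the KNN surrogate.

    ``fit(X, y)`` normalizes the whole input table to [-1, +1], splits it
    into training and validation parts, and searches the mixed space
    (metric index, weighting index, neighbor count, Minkowski exponent) by
    single-objective DA with validation RMSE as the objective.  Discrete
    dimensions are continuous internally and rounded at evaluation time.

    Attributes
    ----------
    best_params_ : dict of the winning hyperparameters.
    result_ : :class:`TuningResult` with train/validation/all metrics and
        the full evaluation log.
    best_estimator_ : KNN model with the winning hyperparameters, refitted
        on the full normalized dataset.
    """

    def __init__(
        self,
        max_iterations: int = 100,
        n_agents: int = 30,
        fraction: float = 0.7,
        seed: int = 0,
    ):
        self.max_iterations = max_iterations
        self.n_agents = n_agents
        self.fraction = fraction
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        self.normalizer_ = fit_normalizer(X)
        Z = self.normalizer_.transform(X)
        train_idx, val_idx = split_train_val(len(y), self.fraction, self.seed)
        if len(val_idx) == 0:
            raise ValueError("validation split is empty")
        Zt, yt = Z[train_idx], y[train_idx]
        Zv, yv = Z[val_idx], y[val_idx]
        n_train = len(train_idx)

        log: list[tuple[dict, float]] = []

        def objective(z: np.ndarray) -> float:
            params = _decode_candidate(z, n_train)
            model = KNNRegressor(**params).fit(Zt, yt)
            rmse = evaluate(model, Zv, yv).rmse
            log.append((params, rmse))
            return rmse

        config = DAConfig(
            lower=np.array([0.0, 0.0, 1.0, 1.0]),
            upper=np.array([float(len(METRICS) - 1), 2.0, float(n_train), 10.0]),
            max_iterations=self.max_iterations,
            n_agents=self.n_agents,
            seed=self.seed,
        )
        baseline = np.array(
            [
                METRICS.index(DEFAULT_KNN_PARAMS["metric"]),
                WEIGHTINGS.index(DEFAULT_KNN_PARAMS["weighting"]),
                min(DEFAULT_KNN_PARAMS["n_neighbors"], n_train),
                2.0,
            ],
            dtype=float,
        )
        result = da_minimize(objective, config, initial_positions=baseline[None, :])

        best_params, best_rmse = min(log, key=lambda item: item[1])
        model = KNNRegressor(**best_params).fit(Zt, yt)
        metrics = {
            "train": evaluate(model, Zt, yt),
            "validation": evaluate(model, Zv, yv),
            "all": evaluate(model, Z, y),
        }
        assert abs(metrics["validation"].rmse - best_rmse) < 1e-12

        self.best_params_ = best_params
        self.result_ = TuningResult(best_params=best_params, metrics=metrics, evaluation_log=log)
        self.train_idx_, self.val_idx_ = train_idx, val_idx
        self.best_estimator_ = KNNRegressor(**best_params).fit(Z, y)
        self.da_result_ = result
        return self

    def predict(self, X):
        Z = self.normalizer_.transform(np.asarray(X, dtype=float))
        return self.best_estimator_.predict(Z)


def tune_knn(
    dataset: BBDDataset,
    response_name: str,
    max_iterations: int = 100,
    n_agents: int = 30,
    fraction: float = 0.7,
    seed: int = 0,
) -> TuningResult:
    """Tune a KNN surrogate of one response of a BBD experiment."""
    tuner = DragonflyKNNTuner(
        max_iterations=max_iterations, n_agents=n_agents, fraction=fraction, seed=seed
    )
    tuner.fit(dataset.actual_matrix(), dataset.response_means(response_name))
    return tuner.result_


# ---------------------------------------------------------------------------
# Desirability optimization of the fitted response surfaces

def optimize_rsm(
    fits: Mapping[str, QuadraticSurfaceRegressor],
    specs: Mapping[str, DesirabilitySpec],
    dataset: BBDDataset,
    grid_resolution: int = 21,
) -> tuple[np.ndarray, dict[str, float], float]:
    """Maximize overall desirability of the fitted surfaces over the factor box.

    A dense regular grid over the coded box seeds a Nelder-Mead refinement.
    When desirability saturates at 1 over a region (every response beyond
    its target anchor), ties break toward the largest summed standardized
    prediction, sum_r (y_r - L_r)/(T_r - L_r), i.e. toward jointly higher
    responses.  Returns (actual-unit optimum, per-response predictions
    there, overall desirability).
    """
    for name, spec in specs.items():
        if name not in fits:
            raise ValueError(f"no fit supplied for response {name!r}")
    k = dataset.spec.k

    def _scores(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(overall desirability, standardized-sum tie-break) per row."""
        log_d = np.zeros(len(points))
        tie = np.zeros(len(points))
        for name, spec in specs.items():
            pred = fits[name].predict(points)
            z = (pred - spec.lower) / (spec.target - spec.lower)
            tie += z
            d = np.clip(z, 0.0, 1.0) ** spec.shape
            with np.errstate(divide="ignore"):
                log_d += np.log(d)
        return np.exp(log_d / len(specs)), tie

    def neg_overall(x_coded: np.ndarray) -> float:
        x_coded = np.clip(x_coded, -1.0, 1.0)
        d, tie = _scores(x_coded[None, :])
        # tiny tie-break term: irrelevant off the saturation plateau
        return -float(d[0]) - 1e-8 * float(tie[0])

    axes = [np.linspace(-1.0, 1.0, grid_resolution)] * k
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.column_stack([m.ravel() for m in mesh])
    scores, ties = _scores(points)
    plateau = scores >= scores.max() - 1e-12
    x0 = points[int(np.argmax(np.where(plateau, ties, -np.inf)))]

    res = sp_optimize.minimize(
        neg_overall,
        x0,
        method="Nelder-Mead",
        bounds=[(-1.0, 1.0)] * k,
        options={"xatol": 1e-7, "fatol": 1e-12, "maxiter": 2000},
    )
    refined = np.clip(res.x, -1.0, 1.0)
    best_coded = refined if _scores(refined[None, :])[0][0] >= scores.max() - 1e-12 else x0
    actual = dataset.spec.decode(best_coded)
    predictions = {
        name: float(fits[name].predict(best_coded[None, :])[0]) for name in specs
    }
    return actual, predictions, float(_scores(best_coded[None, :])[0][0])


# ---------------------------------------------------------------------------
# Multi-objective surrogate optimization

def optimize_knn_moda(
    models: Mapping[str, KNNRegressor],
    normalizer,
    dataset: BBDDataset,
    max_iterations: int = 100,
    n_agents: int = 30,
    seed: int = 0,
    archive_capacity: int = 100,
) -> tuple[ParetoArchive, np.ndarray, dict[str, float]]:
    """MODA maximization of all surrogate responses over the factor domain.

    Surrogates operate on normalized inputs; the search runs in normalized
    space and results are reported in actual units.  The compromise point
    is the archive member with the largest summed predicted response.
    Returns (archive, actual-unit compromise, predictions there).
    """
    names = list(models)
    objectives = [
        (lambda z, m=models[name]: -float(m.predict(np.atleast_2d(z))[0]))
        for name in names
    ]
    config = DAConfig(
        lower=-np.ones(dataset.spec.k),
        upper=np.ones(dataset.spec.k),
        max_iterations=max_iterations,
        n_agents=n_agents,
        seed=seed,
    )
    archive = moda_optimize(objectives, config, archive_capacity=archive_capacity)

    sums = [-np.sum(obj) for obj in archive.objectives]
    best = int(np.argmax(sums))
    z_best = archive.positions[best]
    actual = normalizer.inverse_transform(z_best[None, :])[0]
    predictions = {
        name: float(models[name].predict(z_best[None, :])[0]) for name in names
    }
    return archive, actual, predictions


# ---------------------------------------------------------------------------
# Validation report

def validation_report(
    experimental: Mapping[str, tuple[float, float]],
    predicted: Mapping[str, float],
    sum_label: str = "sum",
) -> pd.DataFrame:
    """Experimental-vs-predicted comparison with absolute errors.

    ``experimental`` maps response -> (mean, sd).  The report appends a
    summed-response row: componentwise sums of the experimental means, of
    the SDs, and of the predictions.
    """
    if set(experimental) != set(predicted):
        raise ValueError("experimental and predicted response sets differ")
    rows = {}
    for name in experimental:
        mean, sd = experimental[name]
        pred = predicted[name]
        rows[name] = {
            "experimental": mean,
            "sd": sd,
            "predicted": pred,
            "error": abs(mean - pred),
        }
    total_mean = sum(v[0] for v in experimental.values())
    total_sd = sum(v[1] for v in experimental.values())
    total_pred = sum(predicted.values())
    rows[sum_label] = {
        "experimental": total_mean,
        "sd": total_sd,
        "predicted": total_pred,
        "error": abs(total_mean - total_pred),
    }
    return pd.DataFrame.from_dict(rows, orient="index")
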