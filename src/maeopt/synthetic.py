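"""Synthetic Box-Behnken experiments from known quadratic ground truth.

The generator emulates the structure of the extraction study: a k-factor
BBD whose response follows a known second-order polynomial, measured in
n_reps replicates with independent homoscedastic Gaussian noise.  Defaults
mirror the study conditions: triplicate measurements and a noise standard
deviation of 2 response units, in the middle of the replicate SDs the
study reports (roughly 0.3 to 4.7 units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import BBDDataset, DesignSpec, Factor, generate_bbd
from .rsm import expand_quadratic
from . import datasets as _datasets

__all__ = ["SyntheticSurfaceSpec", "simulate_bbd_dataset", "make_test_surface"]


def _default_factors(k: int) -> tuple[Factor, ...]:
    return tuple(Factor(f"x{j + 1}", -1.0, 1.0) for j in range(k))


@dataclass
class SyntheticSurfaceSpec:
    """Ground-truth quadratic surface plus a replicate noise model.

    ``beta_int`` is keyed by factor-index pair (i < j); missing pairs are
    zero.  Coefficients are laid out exactly as the response-surface
    fitter's canonical term order, so recovered coefficients compare
    elementwise against :meth:`coefficient_vector`.
    """

    k: int
    beta0: float = 0.0
    beta_lin: tuple[float, ...] = ()
    beta_quad: tuple[float, ...] = ()
    beta_int: dict = field(default_factory=dict)
    noise_sd: float = 2.0
    n_reps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.beta_lin:
            self.beta_lin = (0.0,) * self.k
        if not self.beta_quad:
            self.beta_quad = (0.0,) * self.k
        if len(self.beta_lin) != self.k or len(self.beta_quad) != self.k:
            raise ValueError("coefficient vectors must have length k")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")

    def coefficient_vector(self) -> np.ndarray:
        """Truth in canonical term order (1, x_j, x_i x_j, x_j^2)."""
        from itertools import combinations

        ints = [self.beta_int.get((i, j), 0.0) for i, j in combinations(range(self.k), 2)]
        return np.concatenate(
            [[self.beta0], self.beta_lin, ints, self.beta_quad]
        ).astype(float)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Noise-free surface values at coded points (rows of X)."""
        return expand_quadratic(np.atleast_2d(X)) @ self.coefficient_vector()


def simulate_bbd_dataset(
    spec: SyntheticSurfaceSpec,
    n_center: int = 3,
    factors: tuple[Factor, ...] | None = None,
    response_name: str = "y",
) -> BBDDataset:
    """Simulate a BBD experiment from a known surface.

    Each run's observed record is the mean and sample SD of ``n_reps``
    independent Gaussian replicates around the true surface value.
    """
    design = DesignSpec(factors or _default_factors(spec.k), n_center=n_center)
    if design.k != spec.k:
        raise ValueError("factor count must match the surface dimension")
    runs = generate_bbd(design)
    coded = np.array([r.coded for r in runs])
    truth = spec.evaluate(coded)
    rng = np.random.default_rng(spec.seed)
    reps = truth[:, None] + rng.normal(0.0, spec.noise_sd, size=(len(runs), spec.n_reps))
    means = reps.mean(axis=1)
    sds = reps.std(axis=1, ddof=1) if spec.n_reps > 1 else np.zeros(len(runs))

    observed = pd.DataFrame(
        {
            (response_name, "mean"): means,
            (response_name, "sd"): sds,
            (response_name, "n_reps"): spec.n_reps,
        },
        index=pd.Index([r.run_id for r in runs], name="run_id"),
    )
    observed.columns = pd.MultiIndex.from_tuples(observed.columns)
    return BBDDataset(spec=design, runs=runs, observed=observed)


def _published_surface(response_name: str) -> SyntheticSurfaceSpec:
    coefs = _datasets.published_coefficients(response_name)["estimate"]
    k = 4
    from itertools import combinations

    return SyntheticSurfaceSpec(
        k=k,
        beta0=float(coefs["Intercept"]),
        beta_lin=tuple(float(coefs[f"x{j + 1}"]) for j in range(k)),
        beta_quad=tuple(float(coefs[f"x{j + 1}^2"]) for j in range(k)),
        beta_int={
            (i, j): float(coefs[f"x{i + 1}:x{j + 1}"]) for i, j in combinations(range(k), 2)
        },
        noise_sd=0.0,
        n_reps=1,
    )


def make_test_surface(name: str):
    """Named objective functions with known optima for optimizer testing.

    * ``sphere`` — sum of squares, minimum 0 at the origin (any dimension).
    * ``neg_quadratic_known_max`` — concave paraboloid, maximum 10 at
      (0.3, -0.2); returned as a function to MAXIMIZE.
    * ``fcrc_surface`` / ``alcl3_surface`` — the study's published full
      quadratic models on coded factors (k = 4).
    * ``biobjective_x2`` — pair (x^2, (x-2)^2) on scalars; Pareto set [0, 2].
    """
    if name == "sphere":
        return lambda x: float(np.sum(np.asarray(x, dtype=float) ** 2))
    if name == "neg_quadratic_known_max":
        argmax = np.array([0.3, -0.2])

        def f(x):
            x = np.asarray(x, dtype=float)
            return 10.0 - float(np.sum((x - argmax) ** 2))

        return f
    if name in ("fcrc_surface", "table3_fcrc"):
        surf = _published_surface(_datasets.FCRC)
        return lambda x: float(surf.evaluate(x)[0])
    if name in ("alcl3_surface", "table3_alcl3"):
        surf = _published_surface(_datasets.ALCL3)
        return lambda x: float(surf.evaluate(x)[0])
    if name == "biobjective_x2":
        return (
            lambda x: float(np.asarray(x, dtype=float).ravel()[0] ** 2),
            lambda x: float((np.asarray(x, dtype=float).ravel()[0] - 2.0) ** 2),
        )
    raise ValueError(f"unknown test surface {name!r}")
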