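"""Dragonfly-algorithm optimization, single- and multi-objective.

The dragonfly algorithm (DA) is a swarm metaheuristic in which each agent
combines five steering behaviors — separation (S), alignment (A), cohesion
(C), attraction toward the best solution found so far ("food", F), and
repulsion from the worst ("enemy", E) — into a velocity update

    dX <- (s*S + a*A + c*C + f*F + e*E) + w*dX,     X <- X + dX.

The neighborhood radius grows over iterations, shifting the swarm from
exploration to exploitation; agents with no neighbors take a Levy flight.
Behavior weights follow the canonical schedule: the inertia w anneals
linearly from 0.9 to 0.4, s/a/c are random multiples of a coefficient that
decays from 0.1 to 0 over the first half of the run, f is a random weight
in [0, 2], and e decays with the same coefficient.

The multi-objective variant (MODA) maintains a bounded archive of mutually
non-dominated solutions.  Food is drawn (roulette wheel) from sparsely
populated regions of the archive and the enemy from crowded ones, using a
fixed hypercube segmentation of objective space; on overflow, members are
evicted from the most crowded segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "DAConfig",
    "DAResult",
    "ParetoArchive",
    "dominates",
    "da_minimize",
    "moda_optimize",
]


@dataclass
class DAConfig:
    """Run parameters of a dragonfly optimization.

    ``w_start``/``w_end`` bound the linear inertia anneal; ``behavior_coeff``
    is the initial value of the decaying coefficient that scales the
    separation/alignment/cohesion/enemy weights.
    """

    lower: np.ndarray
    upper: np.ndarray
    max_iterations: int = 100
    n_agents: int = 30
    seed: int = 0
    w_start: float = 0.9
    w_end: float = 0.4
    behavior_coeff: float = 0.1
    levy_exponent: float = 1.5

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape:
            raise ValueError("bound vectors must have equal shape")
        if not np.all(np.isfinite(self.lower)) or not np.all(np.isfinite(self.upper)):
            raise ValueError("bounds must be finite")
        if not np.all(self.lower < self.upper):
            raise ValueError("need lower < upper elementwise")
        if self.max_iterations < 1 or self.n_agents < 1:
            raise ValueError("max_iterations and n_agents must be positive")

    @property
    def dim(self) -> int:
        return self.lower.size


@dataclass
class DAResult:
    """Best solution and per-iteration best-value trace of a DA run."""

    position: np.ndarray
    value: float
    trace: np.ndarray


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """Pareto dominance (minimization): a <= b everywhere, < somewhere."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("objective vectors must have equal length")
    return bool(np.all(a <= b) and np.any(a < b))


class ParetoArchive:
    """Bounded archive of mutually non-dominated (position, objectives) pairs."""

    def __init__(self, capacity: int = 100, n_segments: int = 10):
        if capacity < 1:
            raise ValueError("capacity must be positive")
        self.capacity = capacity
        self.n_segments = n_segments
        self.positions: list[np.ndarray] = []
        self.objectives: list[np.ndarray] = []

    def __len__(self) -> int:
        return len(self.positions)

    def add(self, position: np.ndarray, objective: np.ndarray, rng: np.random.Generator) -> bool:
        """Insert if non-dominated; evict dominated members and, on overflow,
        a member of the most crowded objective-space segment."""
        objective = np.asarray(objective, dtype=float)
        for obj in self.objectives:
            if dominates(obj, objective) or np.array_equal(obj, objective):
                return False
        keep = [i for i, obj in enumerate(self.objectives) if not dominates(objective, obj)]
        self.positions = [self.positions[i] for i in keep]
        self.objectives = [self.objectives[i] for i in keep]
        self.positions.append(np.array(position, dtype=float))
        self.objectives.append(objective)
        if len(self.positions) > self.capacity:
            seg = self._segment_ids()
            counts = np.bincount(seg)
            crowded = np.nonzero(seg == int(np.argmax(counts)))[0]
            victim = int(rng.choice(crowded))
            del self.positions[victim]
            del self.objectives[victim]
        return True

    def _segment_ids(self) -> np.ndarray:
        objs = np.array(self.objectives)
        lo = objs.min(axis=0)
        hi = objs.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        cells = np.minimum(
            (self.n_segments * (objs - lo) / span).astype(int), self.n_segments - 1
        )
        # collapse the per-objective cell indices to one segment id per member
        return np.ravel_multi_index(cells.T, (self.n_segments,) * objs.shape[1])

    def select_food(self, rng: np.random.Generator) -> np.ndarray:
        """Roulette pick favoring members in sparse segments."""
        return self.positions[self._roulette(rng, inverse=True)]

    def select_enemy(self, rng: np.random.Generator) -> np.ndarray:
        """Roulette pick favoring members in crowded segments."""
        return self.positions[self._roulette(rng, inverse=False)]

    def _roulette(self, rng: np.random.Generator, inverse: bool) -> int:
        seg = self._segment_ids()
        counts = np.bincount(seg)[seg].astype(float)
        weights = 1.0 / counts if inverse else counts
        weights /= weights.sum()
        return int(rng.choice(len(weights), p=weights))

    def is_mutually_nondominated(self) -> bool:
        for i, a in enumerate(self.objectives):
            for j, b in enumerate(self.objectives):
                if i != j and dominates(a, b):
                    return False
        return True


def _levy(rng: np.random.Generator, dim: int, beta: float) -> np.ndarray:
    """Levy-flight step (Mantegna's algorithm)."""
    sigma = (
        math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
        / (math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
    ) ** (1 / beta)
    r1 = rng.standard_normal(dim) * sigma
    r2 = rng.standard_normal(dim)
    return 0.01 * r1 / np.abs(r2) ** (1 / beta)


def _schedule(cfg: DAConfig, it: int, rng: np.random.Generator):
    """Iteration-dependent behavior weights (s, a, c, f, e, w) and radius."""
    t = it / cfg.max_iterations
    w = cfg.w_start - it * (cfg.w_start - cfg.w_end) / cfg.max_iterations
    my_c = cfg.behavior_coeff - it * cfg.behavior_coeff / (cfg.max_iterations / 2)
    my_c = max(my_c, 0.0)
    s = 2.0 * rng.random() * my_c
    a = 2.0 * rng.random() * my_c
    c = 2.0 * rng.random() * my_c
    f = 2.0 * rng.random()
    e = my_c
    span = cfg.upper - cfg.lower
    radius = span / 4.0 + span * t * 2.0
    return s, a, c, f, e, w, radius


def _da_step(
    X: np.ndarray,
    dX: np.ndarray,
    food: np.ndarray,
    enemy: np.ndarray,
    cfg: DAConfig,
    it: int,
    rng: np.random.Generator,
) -> None:
    """One synchronous swarm update (in place)."""
    n, dim = X.shape
    s, a, c, f, e, w, radius = _schedule(cfg, it, rng)
    step_max = (cfg.upper - cfg.lower) / 10.0
    X_old = X.copy()
    dX_old = dX.copy()
    for i in range(n):
        diff = np.abs(X_old - X_old[i])
        mask = np.all(diff <= radius, axis=1) & np.any(diff > 0, axis=1)
        neighbors = np.nonzero(mask)[0]
        nn = len(neighbors)
        if nn > 0:
            S = -np.sum(X_old[neighbors] - X_old[i], axis=0)
            A = dX_old[neighbors].mean(axis=0) if nn > 1 else dX_old[i].copy()
            Cpos = X_old[neighbors].mean(axis=0) if nn > 1 else X_old[i].copy()
            C = Cpos - X_old[i]
        else:
            S = np.zeros(dim)
            A = dX_old[i].copy()
            C = np.zeros(dim)
        food_near = np.all(np.abs(X_old[i] - food) <= radius)
        if food_near:
            F = food - X_old[i]
            E = enemy + X_old[i]
            dX[i] = s * S + a * A + c * C + f * F + e * E + w * dX_old[i]
            np.clip(dX[i], -step_max, step_max, out=dX[i])
            X[i] = X_old[i] + dX[i]
        elif nn > 0:
            dX[i] = (
                w * dX_old[i]
                + rng.random() * A
                + rng.random() * C
                + rng.random() * S
            )
            np.clip(dX[i], -step_max, step_max, out=dX[i])
            X[i] = X_old[i] + dX[i]
        else:
            X[i] = X_old[i] + _levy(rng, dim, cfg.levy_exponent) * X_old[i]
            dX[i] = 0.0
        # clip to bounds, zeroing the offending step component
        low = X[i] < cfg.lower
        high = X[i] > cfg.upper
        X[i] = np.clip(X[i], cfg.lower, cfg.upper)
        dX[i][low | high] = 0.0


def da_minimize(
    objective: Callable[[np.ndarray], float],
    config: DAConfig,
    initial_positions: np.ndarray | None = None,
) -> DAResult:
    """Minimize a scalar objective on a box with the dragonfly algorithm.

    ``initial_positions`` optionally seeds (part of) the initial swarm with
    known-good candidates; remaining agents start uniformly at random.
    Returns the best visited solution and the per-iteration best-value
    trace (non-increasing by construction).
    """
    rng = np.random.default_rng(config.seed)
    dim = config.dim
    n = config.n_agents
    X = config.lower + rng.random((n, dim)) * (config.upper - config.lower)
    if initial_positions is not None:
        seeds = np.atleast_2d(np.asarray(initial_positions, dtype=float))
        m = min(len(seeds), n)
        X[:m] = np.clip(seeds[:m], config.lower, config.upper)
    dX = (rng.random((n, dim)) * 2 - 1) * (config.upper - config.lower) / 10.0

    def eval_all(P: np.ndarray) -> np.ndarray:
        vals = np.array([float(objective(p)) for p in P])
        if not np.all(np.isfinite(vals)):
            raise ValueError("objective returned a non-finite value")
        return vals

    values = eval_all(X)
    best_i = int(np.argmin(values))
    best_pos = X[best_i].copy()
    best_val = float(values[best_i])
    trace = np.empty(config.max_iterations)

    for it in range(config.max_iterations):
        worst_i = int(np.argmax(values))
        _da_step(X, dX, best_pos, X[worst_i], config, it, rng)
        values = eval_all(X)
        cur_i = int(np.argmin(values))
        if values[cur_i] < best_val:
            best_val = float(values[cur_i])
            best_pos = X[cur_i].copy()
        trace[it] = best_val

    return DAResult(position=best_pos, value=best_val, trace=trace)


def moda_optimize(
    objectives: Sequence[Callable[[np.ndarray], float]],
    config: DAConfig,
    archive_capacity: int = 100,
    n_segments: int = 10,
) -> ParetoArchive:
    """Multi-objective dragonfly optimization (all objectives minimized).

    Returns the Pareto archive of mutually non-dominated solutions found.
    """
    if len(objectives) < 2:
        raise ValueError("moda_optimize needs at least two objectives")
    rng = np.random.default_rng(config.seed)
    dim = config.dim
    n = config.n_agents
    X = config.lower + rng.random((n, dim)) * (config.upper - config.lower)
    dX = (rng.random((n, dim)) * 2 - 1) * (config.upper - config.lower) / 10.0

    def eval_point(p: np.ndarray) -> np.ndarray:
        vals = np.array([float(f(p)) for f in objectives])
        if not np.all(np.isfinite(vals)):
            raise ValueError("objective returned a non-finite value")
        return vals

    archive = ParetoArchive(capacity=archive_capacity, n_segments=n_segments)
    for i in range(n):
        archive.add(X[i], eval_point(X[i]), rng)

    for it in range(config.max_iterations):
        food = archive.select_food(rng)
        enemy = archive.select_enemy(rng)
        _da_step(X, dX, food, enemy, config, it, rng)
        for i in range(n):
            archive.add(X[i], eval_point(X[i]), rng)

    return archive
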