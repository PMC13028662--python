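"""Box-Behnken designs, factor coding, and colorimetric-assay arithmetic.

A Box-Behnken design (BBD) for k factors places runs at the midpoints of
the edges of the factor hypercube: for every unordered pair of factors the
four combinations (+/-1, +/-1) are run with all remaining factors at their
center level, plus C0 replicated all-center runs.  The total run count is
N = 2k(k-1) + C0.  Factor levels are coded linearly so that the low,
center, and high actual levels map to -1, 0, +1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "DesignSpec",
    "DesignRun",
    "BBDDataset",
    "AssayReading",
    "bbd_run_count",
    "generate_bbd",
    "code_level",
    "decode_level",
    "pattern_of",
    "coded_of",
    "dpph_inhibition",
]

#: ASCII symbols accepted in run patterns; typographic minus variants are
#: normalized to "-" on parsing.
_PATTERN_SYMBOLS = {"+": 1.0, "-": -1.0, "0": 0.0}
_MINUS_VARIANTS = "−–—"  # − – —


@dataclass(frozen=True)
class Factor:
    """A continuous process factor with its actual low/high levels.

    The coded transform is linear: ``coded = (actual - center) / half_range``
    with ``center = (low + high) / 2`` and ``half_range = (high - low) / 2``.
    """

    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(
                f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)


@dataclass(frozen=True)
class DesignSpec:
    """Factors plus the number of replicated center points of a BBD."""

    factors: tuple[Factor, ...]
    n_center: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        if len(self.factors) < 3:
            raise ValueError(
                f"Box-Behnken designs need at least 3 factors, got {len(self.factors)}"
            )
        if self.n_center < 0:
            raise ValueError("n_center must be non-negative")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate factor names: {names}")

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return bbd_run_count(self.k, self.n_center)

    def code(self, actual: Sequence[float]) -> np.ndarray:
        """Vector version of :func:`code_level` over all factors."""
        return np.array(
            [code_level(a, f) for a, f in zip(actual, self.factors, strict=True)]
        )

    def decode(self, coded: Sequence[float]) -> np.ndarray:
        return np.array(
            [decode_level(c, f) for c, f in zip(coded, self.factors, strict=True)]
        )


@dataclass(frozen=True)
class DesignRun:
    """A single design run: identifier, pattern string, coded and actual levels."""

    run_id: int
    pattern: str
    coded: tuple[float, ...]
    actual: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "coded", tuple(float(c) for c in self.coded))
        object.__setattr__(self, "actual", tuple(float(a) for a in self.actual))
        if self.run_id < 1:
            raise ValueError("run_id must be a positive integer")
        if len(self.pattern) != len(self.coded):
            raise ValueError("pattern length must equal the number of factors")


@dataclass
class BBDDataset:
    """A BBD with per-run observed response summaries (mean, sd, n_reps).

    ``observed`` is indexed by run_id with one column triple
    ``(response, {mean, sd, n_reps})`` per response.  ``predicted`` optionally
    carries externally reported model predictions per response (used by the
    packaged study dataset for regression testing).
    """

    spec: DesignSpec
    runs: list[DesignRun]
    observed: pd.DataFrame
    predicted: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        run_ids = [r.run_id for r in self.runs]
        if len(set(run_ids)) != len(run_ids):
            raise ValueError("duplicate run_ids")
        if sorted(self.observed.index) != sorted(run_ids):
            raise ValueError("observed table must have one record per run")
        if (self.observed.xs("sd", axis=1, level=1) < 0).any().any():
            raise ValueError("standard deviations must be non-negative")

    @property
    def response_names(self) -> list[str]:
        return list(self.observed.columns.get_level_values(0).unique())

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def coded_matrix(self) -> np.ndarray:
        return np.array([r.coded for r in self.runs])

    def actual_matrix(self) -> np.ndarray:
        return np.array([r.actual for r in self.runs])

    def response_means(self, name: str) -> np.ndarray:
        s = self.observed[(name, "mean")]
        return s.loc[[r.run_id for r in self.runs]].to_numpy(dtype=float)

    def response_sds(self, name: str) -> np.ndarray:
        s = self.observed[(name, "sd")]
        return s.loc[[r.run_id for r in self.runs]].to_numpy(dtype=float)

    def center_run_ids(self) -> set[int]:
        return {r.run_id for r in self.runs if all(c == 0.0 for c in r.coded)}


@dataclass(frozen=True)
class AssayReading:
    """Control and sample absorbances of a radical-scavenging assay."""

    a_control: float
    a_sample: float

    def __post_init__(self) -> None:
        if self.a_control < 0 or self.a_sample < 0:
            raise ValueError("absorbances must be non-negative")


def bbd_run_count(k: int, n_center: int) -> int:
    """Number of runs of a k-factor BBD with ``n_center`` center points.

    N = 2k(k-1) + C0: four edge-midpoint runs per factor pair plus the
    replicated center.
    """
    if k < 3:
        raise ValueError(f"Box-Behnken designs need k >= 3, got k={k}")
    if n_center < 0:
        raise ValueError("n_center must be non-negative")
    return 2 * k * (k - 1) + n_center


def code_level(actual: float, factor: Factor) -> float:
    """Map an actual factor level to its coded value (low/center/high -> -1/0/+1)."""
    return (actual - factor.center) / factor.half_range


def decode_level(coded: float, factor: Factor) -> float:
    """Inverse of :func:`code_level`."""
    return factor.center + coded * factor.half_range


def pattern_of(coded: Iterable[float]) -> str:
    """Render a coded vector at design levels {-1, 0, +1} as a pattern string."""
    out = []
    for c in coded:
        if c == 1:
            out.append("+")
        elif c == -1:
            out.append("-")
        elif c == 0:
            out.append("0")
        else:
            raise ValueError(
                f"coded value {c} is not a design level (-1, 0, +1); "
                "pattern not representable"
            )
    return "".join(out)


def coded_of(pattern: str) -> np.ndarray:
    """Parse a pattern string of {+, -, 0} into a coded vector."""
    normalized = pattern
    for m in _MINUS_VARIANTS:
        normalized = normalized.replace(m, "-")
    try:
        return np.array([_PATTERN_SYMBOLS[ch] for ch in normalized])
    except KeyError as exc:
        raise ValueError(f"invalid pattern symbol {exc.args[0]!r} in {pattern!r}") from None


def generate_bbd(spec: DesignSpec) -> list[DesignRun]:
    """Construct the runs of a Box-Behnken design in canonical order.

    Factor pairs are enumerated lexicographically; within a pair the four
    (+/-1, +/-1) combinations appear in the order (-,-), (-,+), (+,-), (+,+).
    The ``n_center`` all-zero runs come last.
    """
    k = spec.k
    coded_rows: list[np.ndarray] = []
    for i, j in combinations(range(k), 2):
        for li, lj in product((-1.0, 1.0), repeat=2):
            row = np.zeros(k)
            row[i], row[j] = li, lj
            coded_rows.append(row)
    coded_rows.extend(np.zeros(k) for _ in range(spec.n_center))

    runs = []
    for rid, coded in enumerate(coded_rows, start=1):
        runs.append(
            DesignRun(
                run_id=rid,
                pattern=pattern_of(coded),
                coded=tuple(coded),
                actual=tuple(spec.decode(coded)),
            )
        )
    assert len(runs) == spec.n_runs
    return runs


def dpph_inhibition(reading: AssayReading) -> float:
    """Percent inhibition of the DPPH radical: (A_control - A_sample)/A_control * 100."""
    if reading.a_control <= 0:
        raise ValueError("control absorbance must be positive")
    return (reading.a_control - reading.a_sample) / reading.a_control * 100.0
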