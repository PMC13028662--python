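"""Readers, writers, and JSON serialization shared by the pipeline stages.

The dataset CSV dialect has one header row and the columns::

    run_id, pattern, <factor name per factor>, <response>_mean, <response>_sd

with UTF-8 encoding and "." as the decimal separator.  Factor definitions
travel separately as a JSON design spec (name/low/high/units, n_center).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import BBDDataset, DesignRun, DesignSpec, Factor, pattern_of
from .rsm import QuadraticSurfaceRegressor

__all__ = [
    "read_dataset",
    "write_dataset",
    "design_spec_to_json",
    "design_spec_from_json",
    "fit_to_json",
    "fit_from_json",
]


def design_spec_to_json(spec: DesignSpec, path: str | Path) -> None:
    payload = {
        "factors": [
            {"name": f.name, "low": f.low, "high": f.high, "units": f.units}
            for f in spec.factors
        ],
        "n_center": spec.n_center,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def design_spec_from_json(path: str | Path) -> DesignSpec:
    payload = json.loads(Path(path).read_text())
    factors = tuple(
        Factor(f["name"], float(f["low"]), float(f["high"]), f.get("units", ""))
        for f in payload["factors"]
    )
    return DesignSpec(factors, n_center=int(payload["n_center"]))


def write_dataset(dataset: BBDDataset, path: str | Path) -> None:
    """Write a dataset in the CSV design dialect (full float precision)."""
    rows = []
    for run in dataset.runs:
        row: dict = {"run_id": run.run_id, "pattern": run.pattern}
        for f, a in zip(dataset.spec.factors, run.actual):
            row[f.name] = repr(a)
        for resp in dataset.response_names:
            row[f"{resp}_mean"] = repr(float(dataset.observed.loc[run.run_id, (resp, "mean")]))
            row[f"{resp}_sd"] = repr(float(dataset.observed.loc[run.run_id, (resp, "sd")]))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dataset(path: str | Path, spec: DesignSpec, n_reps: int = 3) -> BBDDataset:
    """Read a dataset CSV against a design spec.

    Malformed content (missing columns, non-numeric cells, duplicate
    run_ids, no data rows) raises ``ValueError`` naming the problem and,
    for cell-level errors, the offending line.
    """
    df = pd.read_csv(path, dtype={"pattern": str})
    required = ["run_id", "pattern"] + [f.name for f in spec.factors]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"dataset file missing column(s): {missing}")
    if len(df) == 0:
        raise ValueError("dataset file contains no runs")
    if df["run_id"].duplicated().any():
        dups = df.loc[df["run_id"].duplicated(), "run_id"].tolist()
        raise ValueError(f"duplicate run_ids: {dups}")

    responses = sorted(
        {c[: -len("_mean")] for c in df.columns if c.endswith("_mean")}
    )
    if not responses:
        raise ValueError("dataset file has no <response>_mean column")
    for resp in responses:
        if f"{resp}_sd" not in df.columns:
            raise ValueError(f"dataset file missing column(s): ['{resp}_sd']")

    numeric_cols = [f.name for f in spec.factors] + [
        f"{r}_{s}" for r in responses for s in ("mean", "sd")
    ]
    for col in numeric_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(f"non-numeric value in column {col!r} at line {line}")
        df[col] = parsed

    runs = []
    obs_rows = {}
    for _, rec in df.iterrows():
        rid = int(rec["run_id"])
        actual = np.array([rec[f.name] for f in spec.factors], dtype=float)
        coded = spec.code(actual)
        runs.append(
            DesignRun(run_id=rid, pattern=str(rec["pattern"]),
                      coded=tuple(coded), actual=tuple(actual))
        )
        obs_rows[rid] = {
            (r, s): (float(rec[f"{r}_{s}"]) if s != "n_reps" else n_reps)
            for r in responses
            for s in ("mean", "sd", "n_reps")
        }
    observed = pd.DataFrame.from_dict(obs_rows, orient="index")
    observed.columns = pd.MultiIndex.from_tuples(observed.columns)
    observed.index.name = "run_id"
    return BBDDataset(spec=spec, runs=runs, observed=observed)


def fit_to_json(fit: QuadraticSurfaceRegressor, path: str | Path) -> None:
    """Serialize a fitted response surface (coefficients, tests, ANOVA)."""
    report = fit.anova()
    payload = {
        "response_name": fit.response_name,
        "k": fit.n_features_in_,
        "coefficients": [
            {
                "term": t,
                "estimate": float(est),
                "se": float(se),
                "t": float(tv),
                "p_value": float(pv),
            }
            for t, est, se, tv, pv in zip(
                fit.term_names_, fit.coef_, fit.se_, fit.tvalues_, fit.pvalues_
            )
        ],
        "anova": {
            "r2": report.r2,
            "r2_adj": report.r2_adj,
            "rmse": report.rmse,
            "model_f": report.model_f,
            "model_p": report.model_p,
            "lof_f": report.lof_f,
            "lof_p": report.lof_p,
        },
        "sse": fit.sse_,
        "sst": fit.sst_,
        "residual_df": fit.residual_df_,
        "X_fit": fit.X_fit_.tolist(),
        "y_fit": fit.y_fit_.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def fit_from_json(path: str | Path) -> QuadraticSurfaceRegressor:
    """Rebuild a fitted response surface from its JSON serialization."""
    payload = json.loads(Path(path).read_text())
    fit = QuadraticSurfaceRegressor(response_name=payload["response_name"])
    fit.fit(np.array(payload["X_fit"]), np.array(payload["y_fit"]))
    stored = np.array([c["estimate"] for c in payload["coefficients"]])
    if not np.allclose(stored, fit.coef_, atol=1e-9):
        raise ValueError("stored coefficients do not match the stored data; file corrupted")
    return fit
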