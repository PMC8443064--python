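"""Cyclic MA-LOESS normalization across multiple samples.

Sequencing intensities from heterogeneous sources carry smooth,
intensity-dependent biases.  For a pair of samples, M = log2(x1) - log2(x2)
and A = the average log2 intensity; under the assumption that most rows are
unchanged between samples, the M-vs-A trend should sit at M = 0.  A robust
local regression (LOESS) of M on A captures the bias, and half of the
fitted trend is charged against each sample of the pair.  Cycling over all
unordered sample pairs and averaging the per-sample corrections
generalizes the pairwise method to any number of samples.

Corrections are fitted on genome-wide bins (or on the table itself) and
stored as piecewise-linear curves on a fixed A-grid so they can be applied
to any other positive table over the same samples — in particular to
regulatory regions whose bias is assumed to follow the genome-wide trend.
Rows containing a zero in any sample are discarded before fitting, because
a zero cannot be attributed to absence of signal versus dropout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .intervals import SchemaError

__all__ = [
    "NormalizationModel",
    "drop_zero_rows",
    "ma_transform",
    "fit_cyclic_loess",
    "apply_correction",
    "normalize_table",
]


def drop_zero_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Remove every row containing a zero in any sample column."""
    numeric = table.select_dtypes(include=[np.number])
    keep = (numeric > 0).all(axis=1)
    if not keep.any():
        raise ValueError("all rows contain zeros; nothing left to normalize")
    return table.loc[keep]


def ma_transform(
    x1: np.ndarray | float, x2: np.ndarray | float, a_mode: str = "mean_log"
) -> tuple[np.ndarray, np.ndarray]:
    """(M, A) for a pair of strictly positive intensity vectors.

    ``a_mode="mean_log"`` uses A = (log2 x1 + log2 x2) / 2 (the microarray
    convention); ``a_mode="log_mean"`` uses A = log2((x1 + x2) / 2).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(x1 <= 0) or np.any(x2 <= 0):
        raise ValueError("MA transform requires strictly positive intensities")
    l1, l2 = np.log2(x1), np.log2(x2)
    m = l1 - l2
    if a_mode == "mean_log":
        a = (l1 + l2) / 2.0
    elif a_mode == "log_mean":
        a = np.log2((x1 + x2) / 2.0)
    else:
        raise ValueError(f"a_mode must be mean_log|log_mean, got {a_mode!r}")
    return m, a


@dataclass
class NormalizationModel:
    """Per-sample correction curves c_s(A) on a fixed A-grid.

    Curves are piecewise linear between grid points with constant
    extrapolation beyond the fitted A-range.  They are balanced by
    construction: sum_s c_s(A) = 0 at every grid point, so applying the
    model preserves each row's average log2 intensity.
    """

    samples: list[str]
    a_grid: np.ndarray
    curves: np.ndarray  # shape (n_samples, grid)
    span: float = 2.0 / 3.0
    a_mode: str = "mean_log"
    rounds_run: int = 0
    subset_size: int = 5000
    seed: int = 0

    def correction(self, sample: str, a_values: np.ndarray) -> np.ndarray:
        s = self.samples.index(sample)
        return np.interp(a_values, self.a_grid, self.curves[s])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "samples": self.samples,
            "a_grid": self.a_grid.tolist(),
            "curves": self.curves.tolist(),
            "span": self.span,
            "a_mode": self.a_mode,
            "rounds_run": self.rounds_run,
            "subset_size": self.subset_size,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            samples=list(payload["samples"]),
            a_grid=np.asarray(payload["a_grid"], dtype=float),
            curves=np.asarray(payload["curves"], dtype=float),
            span=payload["span"],
            a_mode=payload["a_mode"],
            rounds_run=payload["rounds_run"],
            subset_size=payload["subset_size"],
            seed=payload["seed"],
        )


def _row_a(logs: np.ndarray, values: np.ndarray, a_mode: str) -> np.ndarray:
    if a_mode == "mean_log":
        return logs.mean(axis=1)
    return np.log2(values.mean(axis=1))


def fit_cyclic_loess(
    table: pd.DataFrame,
    span: float = 2.0 / 3.0,
    max_rounds: int = 3,
    tol: float = 0.01,
    subset_size: int = 5000,
    seed: int = 0,
    a_mode: str = "mean_log",
    grid_points: int = 256,
    robust_iters: int = 3,
) -> NormalizationModel:
    """Fit balanced per-sample LOESS correction curves.

    Each round, for every unordered pair of samples, M is regressed on A
    (robust local linear fit with the given ``span``) over a seeded subset
    of at most ``subset_size`` rows; half the fitted trend is charged
    against each sample and the per-sample totals, averaged over the pairs
    a sample participates in, are applied in log2 space at the end of the
    round.  Iteration stops when the largest per-sample mean absolute
    applied correction drops below ``tol`` (log2 units) or after
    ``max_rounds`` rounds.  The cumulative corrections, evaluated on a
    ``grid_points``-point A-grid, form the returned model.
    """
    numeric = table.select_dtypes(include=[np.number])
    samples = list(numeric.columns)
    if len(samples) < 2:
        raise ValueError("cyclic LOESS needs at least 2 samples")
    values = numeric.to_numpy(dtype=float)
    if values.shape[0] < 20:
        raise ValueError("need at least 20 rows to fit a correction")
    if np.any(values <= 0):
        raise ValueError("table must be strictly positive; run drop_zero_rows first")

    n_rows, n_samples = values.shape
    logs = np.log2(values)
    rng = np.random.default_rng(seed)
    if n_rows > subset_size:
        subset = np.sort(rng.choice(n_rows, size=subset_size, replace=False))
    else:
        subset = np.arange(n_rows)

    grid = np.linspace(logs.min(), logs.max(), grid_points)
    cumulative = np.zeros((n_samples, grid_points))
    rounds_run = 0

    for _ in range(max_rounds):
        round_curves = np.zeros((n_samples, grid_points))
        for i in range(n_samples - 1):
            for j in range(i + 1, n_samples):
                m, a = ma_transform(values[subset, i], values[subset, j], a_mode)
                fitted = lowess(
                    m, a, frac=span, it=robust_iters, return_sorted=True
                )
                trend = np.interp(grid, fitted[:, 0], fitted[:, 1])
                round_curves[i] += trend / 2.0
                round_curves[j] -= trend / 2.0
        round_curves /= n_samples - 1

        row_a = _row_a(logs, values, a_mode)
        applied = np.empty_like(logs)
        for s in range(n_samples):
            applied[:, s] = np.interp(row_a, grid, round_curves[s])
        logs = logs - applied
        values = 2.0**logs
        cumulative += round_curves
        rounds_run += 1
        if np.abs(applied).mean(axis=0).max() < tol:
            break

    return NormalizationModel(
        samples=samples,
        a_grid=grid,
        curves=cumulative,
        span=span,
        a_mode=a_mode,
        rounds_run=rounds_run,
        subset_size=subset_size,
        seed=seed,
    )


def apply_correction(model: NormalizationModel, table: pd.DataFrame) -> pd.DataFrame:
    """Apply a fitted model to any strictly positive table over the same
    samples.  Each row's A is computed from its own values; corrections use
    constant extrapolation outside the fitted A-range."""
    numeric = table.select_dtypes(include=[np.number])
    if list(numeric.columns) != model.samples:
        raise SchemaError(
            f"table samples {list(numeric.columns)} do not match model "
            f"samples {model.samples}"
        )
    values = numeric.to_numpy(dtype=float)
    if np.any(values <= 0):
        raise ValueError("table must be strictly positive; run drop_zero_rows first")
    logs = np.log2(values)
    row_a = _row_a(logs, values, model.a_mode)
    corrected = np.empty_like(logs)
    for s, sample in enumerate(model.samples):
        corrected[:, s] = logs[:, s] - model.correction(sample, row_a)
    out = table.copy()
    out[model.samples] = 2.0**corrected
    return out


def normalize_table(table: pd.DataFrame, **fit_kwargs) -> tuple[pd.DataFrame, NormalizationModel]:
    """Convenience: drop zero rows, fit on the table itself, apply."""
    clean = drop_zero_rows(table)
    model = fit_cyclic_loess(clean, **fit_kwargs)
    return apply_correction(model, clean), model
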