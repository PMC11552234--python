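"""Statistical primitives: log2 transform, Welch's t-test, BH adjustment.

These are implemented directly from their defining formulas (the only
library call is the t-distribution survival function) so that each one can
be checked against an independent reference implementation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

__all__ = [
    "TestResult",
    "log2_transform",
    "welch_t_test",
    "welch_t_test_matrix",
    "bh_adjust",
]


@dataclass(frozen=True)
class TestResult:
    """One Welch test: the log2 mean difference, t, Satterthwaite df and
    two-sided p.  ``flag`` is 'ok' or 'degenerate' (both variances zero)."""

    estimate: float
    t_statistic: float
    df: float
    p_value: float
    flag: str = "ok"


def log2_transform(values, pseudocount: float = 1.0):
    """Elementwise ``log2(x + pseudocount)``.

    ``pseudocount`` must be positive whenever zeros are present, which is
    the norm for count-derived expression values.
    """
    arr = np.asarray(values, dtype=float) if not isinstance(
        values, (pd.DataFrame, pd.Series)
    ) else values
    if pseudocount <= 0 and (np.asarray(arr) == 0).any():
        raise ValueError(
            f"pseudocount must be > 0 when zeros are present, got {pseudocount}"
        )
    if np.any(np.asarray(arr) + pseudocount <= 0):
        raise ValueError("log2_transform needs x + pseudocount > 0 everywhere")
    if isinstance(values, (pd.DataFrame, pd.Series)):
        return np.log2(values + pseudocount)
    return np.log2(arr + pseudocount)


def welch_t_test_matrix(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch's t-test of ``X`` (genes x n_x) against ``Y``.

    Returns (estimate, t, df, p, degenerate) arrays.  The estimate is the
    difference of row means, ``mean(X) - mean(Y)``; p is two-sided from
    the t distribution with Welch-Satterthwaite degrees of freedom

        df = (sx2/nx + sy2/ny)^2 /
             [ (sx2/nx)^2/(nx-1) + (sy2/ny)^2/(ny-1) ].

    Rows where both sample variances are zero are flagged degenerate and
    get p = 1 if the means agree, else p = 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    nx, ny = X.shape[1], Y.shape[1]
    if nx < 2 or ny < 2:
        raise ValueError(
            f"Welch's t-test needs >= 2 observations per group, got {nx} and {ny}"
        )
    mx = X.mean(axis=1)
    my = Y.mean(axis=1)
    vx = X.var(axis=1, ddof=1)
    vy = Y.var(axis=1, ddof=1)
    estimate = mx - my

    se2 = vx / nx + vy / ny
    degenerate = se2 == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = estimate / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        p = 2.0 * t_dist.sf(np.abs(t), df)
    # Degenerate rows: no within-group variance at all.  Equal means are a
    # perfect null fit (p = 1); unequal means are a zero-variance contrast
    # (p = 0).  t keeps the sign of the estimate.
    with np.errstate(invalid="ignore"):
        t[degenerate] = np.sign(estimate[degenerate]) * np.inf
    t[degenerate & (estimate == 0.0)] = 0.0
    df[degenerate] = np.nan
    p[degenerate] = np.where(estimate[degenerate] == 0.0, 1.0, 0.0)
    return estimate, t, df, p, degenerate


def welch_t_test(x, y) -> TestResult:
    """Welch's unequal-variance t-test of two vectors of log2 values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("welch_t_test expects 1-D vectors")
    est, t, df, p, degen = welch_t_test_matrix(x[None, :], y[None, :])
    return TestResult(
        estimate=float(est[0]),
        t_statistic=float(t[0]),
        df=float(df[0]),
        p_value=float(p[0]),
        flag="degenerate" if degen[0] else "ok",
    )


def bh_adjust(p, m: Optional[int] = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    With the p-values sorted ascending, ``padj_(i) = min_{j>=i} p_(j)*m/j``
    capped at 1, returned in the original order.  ``m`` defaults to
    ``len(p)`` and may be set larger when some tests of the family were
    untestable and excluded.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must all lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than len(p)={p.size}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    padj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    padj_sorted = np.minimum(padj_sorted, 1.0)
    padj = np.empty_like(padj_sorted)
    padj[order] = padj_sorted
    return padj
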