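"""Hotelling's T-squared tests for comparing sets of objective vectors.

The evolved and random-search runs each yield a multivariate summary (the
representative dataset's attribute vector); whether the two groups differ
is tested with the two-sample Hotelling T-squared, the multivariate
generalization of the pooled two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

__all__ = ["HotellingResult", "hotelling_t2", "hotelling_t2_one_sample"]


@dataclass(frozen=True)
class HotellingResult:
    t2: float
    f: float
    df1: int
    df2: int
    p_value: float


def _as_sample(sample, name: str) -> np.ndarray:
    arr = np.asarray(
        [np.asarray(getattr(v, "values", v), dtype=float) for v in sample]
    )
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError(f"{name} must hold at least two vectors")
    return arr


def hotelling_t2(sample_a, sample_b) -> HotellingResult:
    """Two-sample Hotelling T-squared with pooled covariance.

    Accepts sequences of :class:`~epiforge.objectives.ObjectiveVector` or
    plain vectors.  With group sizes n1, n2 and dimension d,

        T2 = (n1 n2 / (n1 + n2)) (m1 - m2)' S_pooled^{-1} (m1 - m2)
        F  = T2 (n1 + n2 - d - 1) / (d (n1 + n2 - 2))

    with F on (d, n1 + n2 - d - 1) degrees of freedom.  A singular pooled
    covariance (e.g. a constant objective across every run) is an error:
    silently pseudo-inverting would fabricate a p-value, so reduce the
    dimension or perturb the design instead.
    """
    a = _as_sample(sample_a, "sample_a")
    b = _as_sample(sample_b, "sample_b")
    if a.shape[1] != b.shape[1]:
        raise ValueError("samples must share the objective dimension")
    n1, n2, d = a.shape[0], b.shape[0], a.shape[1]
    if n1 + n2 <= d + 1:
        raise ValueError(
            f"combined sample size {n1 + n2} must exceed dimension + 1 = {d + 1}"
        )
    diff = a.mean(axis=0) - b.mean(axis=0)
    pooled = ((n1 - 1) * np.cov(a, rowvar=False) + (n2 - 1) * np.cov(b, rowvar=False))
    pooled = np.atleast_2d(pooled) / (n1 + n2 - 2)
    sign, logdet = np.linalg.slogdet(pooled)
    if sign <= 0 or not np.isfinite(logdet):
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; drop constant/collinear objectives "
            "or add replicates rather than pseudo-inverting"
        )
    sol = np.linalg.solve(pooled, diff)
    t2 = float(n1 * n2 / (n1 + n2) * diff @ sol)
    df1, df2 = d, n1 + n2 - d - 1
    f = t2 * df2 / (d * (n1 + n2 - 2))
    p = float(sp_stats.f.sf(f, df1, df2))
    return HotellingResult(t2=t2, f=float(f), df1=df1, df2=df2, p_value=p)


def hotelling_t2_one_sample(sample, mu) -> HotellingResult:
    """One-sample Hotelling T-squared against a hypothesized mean vector."""
    a = _as_sample(sample, "sample")
    mu = np.asarray(mu, dtype=float)
    n, d = a.shape
    if mu.shape != (d,):
        raise ValueError("mu must match the objective dimension")
    if n <= d:
        raise ValueError(f"sample size {n} must exceed dimension {d}")
    diff = a.mean(axis=0) - mu
    cov = np.atleast_2d(np.cov(a, rowvar=False))
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0 or not np.isfinite(logdet):
        raise np.linalg.LinAlgError("sample covariance is singular")
    t2 = float(n * diff @ np.linalg.solve(cov, diff))
    df1, df2 = d, n - d
    f = t2 * (n - d) / (d * (n - 1))
    p = float(sp_stats.f.sf(f, df1, df2))
    return HotellingResult(t2=t2, f=float(f), df1=df1, df2=df2, p_value=p)
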