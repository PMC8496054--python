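"""Shared inferential procedures.

All p-values in this package are two-sided and no multiple-testing
correction is applied anywhere; each stage reports raw per-comparison
p-values.  Group comparisons use the Mann-Whitney U test, associations
the Spearman rank correlation, and the regression lines of the density
analysis ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "OLSResult",
    "mann_whitney",
    "spearman",
    "ols",
    "significance_stars",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-group or association test.

    ``method`` records whether an exact or an approximate reference
    distribution produced ``p_value``.
    """

    name: str
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class OLSResult:
    slope: float
    intercept: float
    residual_variance: float
    n: int


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if np.isnan(arr).any():
        raise ValueError(f"{name} contains NaN")
    return arr


def mann_whitney(group_a, group_b, mode: str = "auto") -> TestResult:
    """Mann-Whitney U test with average-rank tie handling.

    ``mode`` selects the reference distribution:

    * ``"exact"`` — exact enumeration of the U null distribution
      (only valid without ties; with ties present the exact
      distribution ignores the tie structure).
    * ``"normal"`` — normal approximation with tie correction and
      continuity correction.
    * ``"auto"`` — exact when ``n_a + n_b <= 20`` and the pooled data
      are tie-free, normal otherwise.

    The reported statistic is U of ``group_a``.
    """
    a = _as_float_array(group_a, "group_a")
    b = _as_float_array(group_b, "group_b")
    if mode not in {"auto", "exact", "normal"}:
        raise ValueError(f"unknown mode: {mode!r}")

    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        use_exact = (a.size + b.size) <= 20 and not has_ties
    else:
        use_exact = mode == "exact"

    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    detail = "exact enumeration" if use_exact else "normal approximation, tie and continuity corrected"
    return TestResult(
        name="mann-whitney-u",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=detail,
        n=(a.size, b.size),
    )


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with p from the t approximation (n-2 df).

    Ranks are average ranks, so tied data are handled; constant input has
    no defined rank correlation and is rejected.
    """
    xa = _as_float_array(x, "x")
    ya = _as_float_array(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must be paired (equal length)")
    if xa.size < 4:
        raise ValueError(f"need at least 4 pairs, got {xa.size}")
    for name, arr in (("x", xa), ("y", ya)):
        if np.unique(arr).size == 1:
            raise ValueError(f"{name} is constant; rank correlation undefined")
    r, p = sps.spearmanr(xa, ya)
    return TestResult(
        name="spearman-r",
        statistic=float(r),
        p_value=float(p),
        method="t approximation, n-2 df",
        n=(xa.size,),
    )


def ols(x, y) -> OLSResult:
    """Ordinary least squares of ``y`` on ``x`` (closed form)."""
    xa = _as_float_array(x, "x")
    ya = _as_float_array(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must be paired (equal length)")
    if xa.size < 3:
        raise ValueError(f"need at least 3 points, got {xa.size}")
    if np.var(xa) == 0:
        raise ValueError("x has zero variance; slope undefined")
    fit = sps.linregress(xa, ya)
    resid = ya - (fit.intercept + fit.slope * xa)
    dof = xa.size - 2
    return OLSResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residual_variance=float(resid @ resid / dof),
        n=xa.size,
    )


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star label.

    ``***`` for p <= 0.001, ``**`` for p <= 0.01, ``*`` for p <= 0.05,
    ``ns`` otherwise.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"
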