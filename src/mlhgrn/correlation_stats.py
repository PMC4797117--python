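"""Rank correlations, first-order partial correlation, and the delta-method
significance test for the correlation difference D.

The building block of the bottom-up network construction is the triplet
(x, y, z): two same-layer genes x, y and one candidate regulator z.  The
interference of z on the pair is measured by

    D = r_xy - r_xy|z,

the gap between the marginal correlation of the pair and their first-order
partial correlation given z.  D is a smooth function of the three pairwise
correlations (r_xy, r_zy, r_zx); its sampling variance is obtained by the
multivariate delta method,

    var(D) = pd' . Sigma . pd,

where pd is the gradient of D in (r_xy, r_zy, r_zx) and Sigma the asymptotic
covariance matrix of the three sample correlations.  z1 = D / sqrt(var(D)) is
referred to a standard normal.

All correlations here are Spearman rank correlations (midrank ties); the
covariance formulas are the classical product-moment asymptotics applied to
the rank-transformed data.  Calibration of that combination is checked by
simulation in the test suite rather than asserted from theory.

Notes on the covariance matrix
------------------------------
For sample correlations among three jointly Gaussian variables, every pair of
correlations shares one index, and the Pearson-Filon asymptotic covariance of
the two correlations (b, c) sharing an index, with a the third correlation, is

    cov = [(2a - b*c) * (1 - a^2 - b^2 - c^2) + 2a^3] / (2n).

The diagonal is var(r) = (1 - r^2)^2 / n.  The entry assignment used here
(sigma12 pairs r_xy with r_zy, a = r_zx; sigma13 pairs r_xy with r_zx,
a = r_zy; sigma23 pairs r_zy with r_zx, a = r_xy) was confirmed entrywise
against a Monte-Carlo covariance of sample correlations; see the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateConditioningError, DegenerateInputError

#: correlations at or beyond this magnitude are clamped in variance formulas
R_CLAMP = 1.0 - 1e-12

__all__ = [
    "CorrelationTriple",
    "DifferenceTest",
    "spearman_correlation",
    "correlation_pvalue",
    "partial_correlation_first_order",
    "correlation_difference",
    "correlation_covariance",
    "difference_partials",
    "difference_test",
    "batch_difference_test",
]


@dataclass(frozen=True)
class CorrelationTriple:
    """The three pairwise correlations of a gene triplet (x, y, z).

    ``r_xy`` is the pair of interest, ``r_zy`` and ``r_zx`` tie the candidate
    regulator z to each pair member.  Correlation is symmetric, so a single
    canonical orientation is stored.  ``n`` is the common sample count.
    """

    r_xy: float
    r_zy: float
    r_zx: float
    n: int

    def __post_init__(self) -> None:
        for name in ("r_xy", "r_zy", "r_zx"):
            r = getattr(self, name)
            if not np.isfinite(r) or abs(r) > 1.0:
                raise ValueError(f"{name}={r!r} is not a correlation in [-1, 1]")
        if self.n < 4:
            raise ValueError(f"n={self.n}: at least 4 observations are required")


@dataclass
class DifferenceTest:
    """Full output of the delta-method test of H0: D = 0."""

    D: float
    pd: np.ndarray        # gradient (pd1, pd2, pd3) in (r_xy, r_zy, r_zx)
    sigma: np.ndarray     # 3x3 covariance of (r_xy, r_zy, r_zx)
    var_D: float
    D_se: float
    z1: float
    p3: float


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation of two equal-length vectors.

    Ties receive average (mid) ranks.  Raises ``DegenerateInputError`` for a
    constant vector or a length mismatch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise DegenerateInputError(
            f"length mismatch: x has shape {x.shape}, y has shape {y.shape}"
        )
    if x.size < 3:
        raise DegenerateInputError("need at least 3 observations")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise DegenerateInputError(f"vector {name} is constant")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def correlation_pvalue(r, n, *, conditioned_on: int = 0):
    """Two-sided p-value for H0: rho = 0 via the t approximation.

    ``t = r * sqrt(df / (1 - r^2))`` with ``df = n - 2 - conditioned_on``
    degrees of freedom; a first-order partial correlation passes
    ``conditioned_on=1``.  ``|r| = 1`` returns 0 by convention.  Accepts
    scalars or arrays (broadcast).
    """
    r_arr = np.asarray(r, dtype=float)
    n_arr = np.asarray(n)
    if np.any(np.abs(r_arr) > 1.0 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    df = n_arr - 2 - conditioned_on
    if np.any(df < 1):
        raise ValueError("sample size too small for the t approximation")
    r_c = np.clip(r_arr, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_c * np.sqrt(df / (1.0 - r_c**2))
    p = np.where(np.abs(r_c) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df))
    return float(p) if np.isscalar(r) and np.isscalar(n) else p


def _check_conditioning(r_zx, r_zy) -> None:
    if np.any(np.abs(np.asarray(r_zx)) >= 1.0) or np.any(np.abs(np.asarray(r_zy)) >= 1.0):
        raise DegenerateConditioningError(
            "|r_zx| or |r_zy| equals 1: partial correlation denominator is zero"
        )


def _pcor(r_xy, r_zx, r_zy):
    """Vectorized first-order partial correlation (no clipping)."""
    return (r_xy - r_zx * r_zy) / np.sqrt((1.0 - r_zx**2) * (1.0 - r_zy**2))


def partial_correlation_first_order(t: CorrelationTriple) -> float:
    """First-order partial correlation r_xy|z = (r_xy - r_zx r_zy) /
    sqrt((1 - r_zx^2)(1 - r_zy^2)), clipped into [-1, 1] on numeric
    overshoot (with a warning)."""
    _check_conditioning(t.r_zx, t.r_zy)
    p = float(_pcor(t.r_xy, t.r_zx, t.r_zy))
    if abs(p) > 1.0:
        warnings.warn(
            f"partial correlation {p:.6g} outside [-1, 1]; clipping", RuntimeWarning
        )
        p = float(np.clip(p, -1.0, 1.0))
    return p


def correlation_difference(t: CorrelationTriple) -> float:
    """D = r_xy - r_xy|z.  Symmetric under exchange of x and y (i.e. under
    swapping r_zx and r_zy), and exactly 0 when r_zx = r_zy = 0."""
    _check_conditioning(t.r_zx, t.r_zy)
    return float(t.r_xy - _pcor(t.r_xy, t.r_zx, t.r_zy))


def _clamp_r(r):
    """Clamp correlations into (-1, 1) for use in variance formulas."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > R_CLAMP):
        warnings.warn(
            "correlation with |r| >= 1 - 1e-12 clamped in variance formula",
            RuntimeWarning,
        )
    return np.clip(r, -R_CLAMP, R_CLAMP)


def _cov_shared(a, b, c, n):
    """Asymptotic covariance of two sample correlations b, c that share one
    variable; a is the correlation of the remaining pair."""
    s2 = a**2 + b**2 + c**2
    return ((2.0 * a - b * c) * (1.0 - s2) + 2.0 * a**3) / (2.0 * n)


def _sigma_entries(r_xy, r_zy, r_zx, n):
    """The six distinct entries of Sigma, vectorized."""
    s11 = (1.0 - r_xy**2) ** 2 / n
    s22 = (1.0 - r_zy**2) ** 2 / n
    s33 = (1.0 - r_zx**2) ** 2 / n
    s12 = _cov_shared(r_zx, r_xy, r_zy, n)  # r_xy, r_zy share y
    s13 = _cov_shared(r_zy, r_xy, r_zx, n)  # r_xy, r_zx share x
    s23 = _cov_shared(r_xy, r_zy, r_zx, n)  # r_zy, r_zx share z
    return s11, s22, s33, s12, s13, s23


def correlation_covariance(t: CorrelationTriple) -> np.ndarray:
    """3x3 asymptotic covariance matrix of (r_xy, r_zy, r_zx).

    Diagonal (1 - r^2)^2 / n; off-diagonals from the shared-index
    Pearson-Filon formula (module docstring).  Symmetric by construction.
    """
    r_xy, r_zy, r_zx = (float(_clamp_r(r)) for r in (t.r_xy, t.r_zy, t.r_zx))
    s11, s22, s33, s12, s13, s23 = _sigma_entries(r_xy, r_zy, r_zx, t.n)
    return np.array([[s11, s12, s13], [s12, s22, s23], [s13, s23, s33]])


def _partials(r_xy, r_zy, r_zx):
    """Vectorized gradient of D in (r_xy, r_zy, r_zx)."""
    qzx = 1.0 - r_zx**2
    qzy = 1.0 - r_zy**2
    pd1 = 1.0 - 1.0 / (np.sqrt(qzy) * np.sqrt(qzx))
    pd2 = (r_zx - r_xy * r_zy) / (np.sqrt(qzx) * qzy**1.5)
    pd3 = (r_zy - r_xy * r_zx) / (np.sqrt(qzy) * qzx**1.5)
    return pd1, pd2, pd3


def difference_partials(t: CorrelationTriple) -> np.ndarray:
    """Gradient (pd1, pd2, pd3) of D with respect to (r_xy, r_zy, r_zx)."""
    _check_conditioning(t.r_zx, t.r_zy)
    return np.array(_partials(t.r_xy, t.r_zy, t.r_zx), dtype=float)


def difference_test(t: CorrelationTriple) -> DifferenceTest:
    """Assemble the full delta-method test of H0: D = 0.

    var(D) = pd' Sigma pd, clamped at 0 (with a warning) if rounding makes
    the quadratic form negative; z1 = D / sqrt(var(D)); p3 two-sided from the
    standard normal.  The degenerate case D_se = 0 returns p3 = 1 when D = 0
    (nothing to test) and raises otherwise.
    """
    D = correlation_difference(t)
    pd = difference_partials(t)
    sigma = correlation_covariance(t)
    var_D = float(pd @ sigma @ pd)
    if var_D < 0.0:
        warnings.warn("negative delta-method variance clamped to 0", RuntimeWarning)
        var_D = 0.0
    D_se = float(np.sqrt(var_D))
    if D_se == 0.0:
        if D == 0.0:
            return DifferenceTest(D, pd, sigma, var_D, D_se, 0.0, 1.0)
        raise DegenerateConditioningError("D_se = 0 with nonzero D")
    z1 = D / D_se
    p3 = float(2.0 * stats.norm.sf(abs(z1)))
    return DifferenceTest(D, pd, sigma, var_D, D_se, float(z1), p3)


def batch_difference_test(r_xy, r_zy, r_zx, n):
    """Vectorized difference test over arrays of correlation triples.

    Returns a dict of arrays with keys ``pcor``, ``D``, ``var_D``, ``D_se``,
    ``z1``, ``p3``.  Degenerate entries (D_se = 0) get z1 = 0 and p3 = 1.
    Used by the triplet engine, where hundreds of thousands of triplets are
    evaluated per layer.
    """
    r_xy = _clamp_r(r_xy)
    r_zy = _clamp_r(r_zy)
    r_zx = _clamp_r(r_zx)
    pcor = np.clip(_pcor(r_xy, r_zx, r_zy), -1.0, 1.0)
    D = r_xy - _pcor(r_xy, r_zx, r_zy)
    pd1, pd2, pd3 = _partials(r_xy, r_zy, r_zx)
    s11, s22, s33, s12, s13, s23 = _sigma_entries(r_xy, r_zy, r_zx, n)
    var_D = (
        pd1**2 * s11 + pd2**2 * s22 + pd3**2 * s33
        + 2.0 * (pd1 * pd2 * s12 + pd1 * pd3 * s13 + pd2 * pd3 * s23)
    )
    var_D = np.maximum(var_D, 0.0)
    D_se = np.sqrt(var_D)
    with np.errstate(divide="ignore", invalid="ignore"):
        z1 = np.where(D_se > 0.0, D / np.where(D_se > 0.0, D_se, 1.0), 0.0)
    p3 = np.where(D_se > 0.0, 2.0 * stats.norm.sf(np.abs(z1)), 1.0)
    return {"pcor": pcor, "D": D, "var_D": var_D, "D_se": D_se, "z1": z1, "p3": p3}
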