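"""Conventional statistics used alongside the phylogenetic analyses.

Paired t-tests (sexual dimorphism of species means), product-moment
correlations (digit ratio vs body size), and the chi-square quantile used
as the likelihood-ratio critical value.  Tail probabilities are computed
from the regularized incomplete beta / gamma functions, which are the
canonical numerical route for the t and chi-square distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .errors import DataError, UndefinedStatisticError


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    p_value: float


def t_sf_two_sided(t: float, df: int) -> float:
    """Two-sided tail probability of Student's t with ``df`` degrees of freedom.

    Uses P(|T| > t) = I_x(df/2, 1/2) with x = df / (df + t^2), where I is the
    regularized incomplete beta function.
    """
    if df < 1:
        raise DataError(f"degrees of freedom must be >= 1, got {df}")
    t = float(t)
    if not np.isfinite(t):
        return 0.0
    x = df / (df + t * t)
    return float(special.betainc(df / 2.0, 0.5, x))


def chisq_quantile(alpha: float, df: int) -> float:
    """Upper-``alpha`` critical value of the chi-square distribution.

    Returns the (1 - alpha) quantile, computed by inverting the regularized
    lower incomplete gamma function: q = 2 * P^{-1}(df/2, 1 - alpha).
    """
    if not 0.0 < alpha < 1.0:
        raise DataError(f"alpha must be in (0, 1), got {alpha}")
    if df < 1:
        raise DataError(f"degrees of freedom must be >= 1, got {df}")
    return float(2.0 * special.gammaincinv(df / 2.0, 1.0 - alpha))


def paired_t_test(x, y) -> TestResult:
    """Paired t-test of ``x`` against ``y`` (two-sided).

    The pipeline convention is x = female values, y = male values, so a
    male-biased trait yields a negative statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError(
            f"paired samples must be equal-length vectors, got {x.shape} and {y.shape}"
        )
    n = x.size
    if n < 2:
        raise DataError("paired t-test needs n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.allclose(d, 0.0):
            # identical samples: define t = 0, P = 1
            return TestResult(0.0, n - 1, 1.0)
        raise UndefinedStatisticError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    return TestResult(float(t), n - 1, t_sf_two_sided(t, n - 1))


def pearson_correlation(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-based P value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("correlation inputs must be equal-length vectors")
    n = x.size
    if n < 3:
        raise DataError("correlation needs n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc * xc))
    sy = np.sqrt(np.sum(yc * yc))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedStatisticError("correlation undefined for zero variance")
    r = float(np.sum(xc * yc) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        return CorrelationResult(r, df, 0.0)
    t = r * np.sqrt(df / (1.0 - r * r))
    return CorrelationResult(r, df, t_sf_two_sided(t, df))
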