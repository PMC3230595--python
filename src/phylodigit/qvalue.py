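"""Storey q-values with bootstrap estimation of the null proportion.

The q-value of a hypothesis is the smallest positive false discovery rate
at which it would be called significant.  It is computed from the ordered
P values and an estimate of pi0, the proportion of true nulls:
pi0(lambda) = #{p_i > lambda} / (m (1 - lambda)) over a grid of lambda,
with lambda chosen to minimize the bootstrap mean squared error of
pi0(lambda) around the most optimistic (smallest) plug-in estimate.
With pi0 fixed at 1 the procedure reduces exactly to Benjamini-Hochberg
adjusted P values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.0, 0.95, 0.05), 2))


@dataclass
class QValueSet:
    p_values: np.ndarray
    q_values: np.ndarray
    pi0: float
    lambda_: float
    significant: np.ndarray = field(default=None)
    threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.significant is None:
            self.significant = self.q_values < self.threshold


def _pi0_grid(p: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    m = p.size
    return np.array(
        [np.sum(p > lam) / (m * (1.0 - lam)) for lam in lambdas]
    )


def _step_down(p: np.ndarray, pi0: float) -> np.ndarray:
    """q_(i) = min_{j >= i} pi0 * m * p_(j) / j on the ordered P values."""
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate((pi0 * m * p_sorted / ranks)[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def qvalues(
    p,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    B: int = 1000,
    seed: int = 0,
    pi0: float | None = None,
) -> QValueSet:
    """Compute Storey q-values for a family of P values.

    ``pi0`` may be fixed (e.g. 1.0 for a pure Benjamini-Hochberg
    adjustment); otherwise it is estimated on ``lambda_grid`` with ``B``
    bootstrap resamples, deterministically for a fixed ``seed``.
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        raise DataError("empty P value vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DataError("P values must lie in [0, 1]")
    lambdas = np.asarray(lambda_grid, dtype=float)
    if np.any((lambdas < 0) | (lambdas >= 0.95)):
        raise DataError("lambda grid must lie in [0, 0.95)")
    if B < 100:
        raise DataError("need at least 100 bootstrap resamples")

    if pi0 is None:
        pi0_hat = np.clip(_pi0_grid(p, lambdas), None, 1.0)
        target = float(np.min(pi0_hat))
        rng = np.random.default_rng(seed)
        m = p.size
        mse = np.zeros(lambdas.size)
        for _ in range(B):
            pb = p[rng.integers(0, m, size=m)]
            pi0_b = np.clip(_pi0_grid(pb, lambdas), None, 1.0)
            mse += (pi0_b - target) ** 2
        best = int(np.argmin(mse))
        lam = float(lambdas[best])
        pi0_est = float(pi0_hat[best])
        pi0_est = min(max(pi0_est, 1.0 / m), 1.0)  # clip into (0, 1]
    else:
        if not 0.0 < pi0 <= 1.0:
            raise DataError("fixed pi0 must lie in (0, 1]")
        lam = float("nan")
        pi0_est = float(pi0)

    q = _step_down(p, pi0_est)
    return QValueSet(p_values=p, q_values=q, pi0=pi0_est, lambda_=lam)
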