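"""Maximum-likelihood GLS regression and star-vs-tree model comparison.

A trait regressed on a substrate index is fitted twice: once under a star
phylogeny (error covariance = identity; ordinary least squares) and once
under the hierarchical tree (error covariance proportional to the Brownian
shared-path-length matrix; PGLS).  The two fits are compared by a
likelihood-ratio test against the chi-square critical value for 1 df; when
the likelihoods are not distinguishably different the phylogenetic model is
preferred, since species are never truly independent.

Estimates use the ML (not REML) error variance so the log-likelihoods are
directly comparable between the two covariance structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import (
    DataError,
    DegenerateLikelihoodError,
    KeyingError,
    LinearAlgebraError,
    UndefinedStatisticError,
)
from .stats import chisq_quantile, t_sf_two_sided
from .tree import CovarianceMatrix, PhyloTree, assign_branch_lengths, phylo_covariance

STAR = "star"
HIERARCHICAL = "hierarchical"


@dataclass
class RegressionFit:
    """A fitted GLS regression with its ML likelihood."""

    coefficients: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    residuals: np.ndarray
    sigma2_ml: float
    log_likelihood: float
    model: str
    n: int
    k: int
    y: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)

    @property
    def slope(self) -> float:
        """Coefficient of the last (single-predictor) column."""
        return float(self.coefficients[-1])

    @property
    def slope_p(self) -> float:
        return float(self.p_values[-1])


@dataclass(frozen=True)
class ModelChoice:
    lnl_star: float
    lnl_tree: float
    lrt: float
    critical_value: float
    selected: str


def gls_fit(y, X, C: CovarianceMatrix | np.ndarray, model: str = STAR) -> RegressionFit:
    """Generalized least squares with maximum-likelihood error variance.

    beta = (X' C^-1 X)^-1 X' C^-1 y, sigma2 = e' C^-1 e / n (ML), and
    lnL = -0.5 * [n ln(2 pi sigma2) + ln|C| + n].  Coefficient standard
    errors apply the small-sample correction n/(n-k) to the ML variance and
    P values use Student's t on n - k degrees of freedom.

    ``C`` must be symmetric positive definite; a Cholesky failure raises
    :class:`LinearAlgebraError` rather than silently regularizing.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Cm = C.matrix if isinstance(C, CovarianceMatrix) else np.asarray(C, dtype=float)
    n, k = X.shape
    if y.size != n or Cm.shape != (n, n):
        raise DataError(
            f"dimension mismatch: y has {y.size}, X is {X.shape}, C is {Cm.shape}"
        )
    if n <= k:
        raise DataError(f"need n > k, got n={n}, k={k}")
    try:
        cho = linalg.cho_factor(Cm, lower=True)
    except linalg.LinAlgError as exc:
        raise LinearAlgebraError(f"covariance matrix not positive definite: {exc}") from exc
    logdet_C = 2.0 * np.sum(np.log(np.diag(cho[0])))

    Cinv_X = linalg.cho_solve(cho, X)
    Cinv_y = linalg.cho_solve(cho, y)
    XtCiX = X.T @ Cinv_X
    XtCiy = X.T @ Cinv_y
    cond = np.linalg.cond(XtCiX)
    if not np.isfinite(cond) or cond > 1e12:
        raise LinearAlgebraError(f"X'C^-1X ill-conditioned (cond={cond:.3g})")
    try:
        XtCiX_inv = linalg.inv(XtCiX)
    except linalg.LinAlgError as exc:
        raise LinearAlgebraError(f"X'C^-1X singular: {exc}") from exc

    beta = XtCiX_inv @ XtCiy
    e = y - X @ beta
    sigma2 = float(e @ linalg.cho_solve(cho, e) / n)
    if sigma2 <= 0 or sigma2 < 1e-14 * float(y @ y + 1.0):
        raise DegenerateLikelihoodError(
            "ML error variance is (numerically) zero: perfect fit"
        )
    lnl = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet_C + n)

    coef_cov = sigma2 * n / (n - k) * XtCiX_inv
    se = np.sqrt(np.diag(coef_cov))
    tvals = beta / se
    pvals = np.array([t_sf_two_sided(t, n - k) for t in tvals])
    return RegressionFit(
        coefficients=beta,
        std_errors=se,
        p_values=pvals,
        residuals=e,
        sigma2_ml=sigma2,
        log_likelihood=float(lnl),
        model=model,
        n=n,
        k=k,
        y=y,
        X=X,
    )


def ols_fit(y, X) -> RegressionFit:
    """Ordinary least squares: GLS under a star phylogeny (C = I)."""
    n = np.asarray(y).size
    return gls_fit(y, X, np.eye(n), model=STAR)


def lrt_compare(fit_star: RegressionFit, fit_tree: RegressionFit,
                alpha: float = 0.05) -> ModelChoice:
    """Likelihood-ratio choice between the star and hierarchical fits.

    LRT = 2 |lnL_tree - lnL_star| compared with the chi-square critical
    value for 1 df.  The higher-likelihood model is selected only when the
    LRT exceeds the critical value; at or below it the phylogenetic
    (hierarchical) model is preferred.
    """
    if fit_star.n != fit_tree.n or fit_star.k != fit_tree.k or not (
        np.array_equal(fit_star.y, fit_tree.y) and np.array_equal(fit_star.X, fit_tree.X)
    ):
        raise DataError("model comparison requires identical y and X")
    crit = chisq_quantile(alpha, 1)
    lrt = 2.0 * abs(fit_tree.log_likelihood - fit_star.log_likelihood)
    if lrt > crit:
        selected = (
            HIERARCHICAL
            if fit_tree.log_likelihood > fit_star.log_likelihood
            else STAR
        )
    else:
        selected = HIERARCHICAL
    return ModelChoice(
        lnl_star=fit_star.log_likelihood,
        lnl_tree=fit_tree.log_likelihood,
        lrt=float(lrt),
        critical_value=crit,
        selected=selected,
    )


def run_regression_grid(
    trait_table: pd.DataFrame,
    substrate_table: pd.DataFrame,
    tree: PhyloTree,
    traits: list[str] | None = None,
    substrates: list[str] | None = None,
    branch_lengths: str = "nee",
) -> pd.DataFrame:
    """Fit every trait x substrate cell under both covariance models.

    Each cell is a univariate regression of the trait on that single
    substrate index (intercept included), fitted once by OLS (star) and
    once by PGLS with the tree covariance.  Returns a long-format frame
    with one row per trait x substrate x model; a zero-variance substrate
    column yields a row flagged ``degenerate`` instead of a crash.
    """
    traits = list(traits if traits is not None else trait_table.columns)
    substrates = list(
        substrates if substrates is not None else substrate_table.columns
    )
    species = list(trait_table.index)
    missing = set(species).symmetric_difference(substrate_table.index)
    tip_mismatch = set(species).symmetric_difference(tree.tip_labels)
    if missing or tip_mismatch:
        raise KeyingError(
            f"species keying mismatch: tables differ by {sorted(missing)}, "
            f"tree differs by {sorted(tip_mismatch)}"
        )
    if not tree.has_branch_lengths():
        tree = assign_branch_lengths(tree, branch_lengths)
    C = phylo_covariance(tree).reordered(species)

    rows = []
    for trait in traits:
        y = trait_table[trait].to_numpy(dtype=float)
        for sub in substrates:
            x = substrate_table.loc[species, sub].to_numpy(dtype=float)
            X = np.column_stack([np.ones_like(x), x])
            for model, Cmat in ((STAR, np.eye(len(species))), (HIERARCHICAL, C)):
                row = {"trait": trait, "substrate": sub, "model": model}
                try:
                    fit = gls_fit(y, X, Cmat, model=model)
                except (LinearAlgebraError, DegenerateLikelihoodError,
                        UndefinedStatisticError) as exc:
                    row.update(
                        coefficient=np.nan, p_value=np.nan,
                        log_likelihood=np.nan, degenerate=True,
                        note=str(exc),
                    )
                else:
                    row.update(
                        coefficient=fit.slope, p_value=fit.slope_p,
                        log_likelihood=fit.log_likelihood, degenerate=False,
                        note="",
                    )
                rows.append(row)
    grid = pd.DataFrame(rows)

    # attach the model choice per trait x substrate pair
    choices = []
    for (trait, sub), cell in grid.groupby(["trait", "substrate"], sort=False):
        star = cell[cell.model == STAR].iloc[0]
        hier = cell[cell.model == HIERARCHICAL].iloc[0]
        if star.degenerate or hier.degenerate:
            selected, lrt = "", np.nan
        else:
            lrt = 2.0 * abs(hier.log_likelihood - star.log_likelihood)
            if lrt > chisq_quantile(0.05, 1):
                selected = (
                    HIERARCHICAL
                    if hier.log_likelihood > star.log_likelihood
                    else STAR
                )
            else:
                selected = HIERARCHICAL
        choices.append({"trait": trait, "substrate": sub,
                        "lrt": lrt, "selected": selected})
    grid = grid.merge(pd.DataFrame(choices), on=["trait", "substrate"])
    return grid
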