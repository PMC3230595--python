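"""GLS fitting, likelihood-ratio model choice, and the regression grid."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from phylodigit import (
    assign_branch_lengths,
    gls_fit,
    lrt_compare,
    ols_fit,
    phylo_covariance,
    run_regression_grid,
)
from phylodigit.errors import (
    DataError,
    DegenerateLikelihoodError,
    LinearAlgebraError,
)
from phylodigit.regression import HIERARCHICAL, STAR, RegressionFit

from conftest import random_tree


def make_fit(lnl, model=STAR):
    """A minimal RegressionFit stub sharing y/X for LRT-rule tests."""
    y = np.arange(4.0)
    X = np.column_stack([np.ones(4), np.arange(4.0)])
    return RegressionFit(
        coefficients=np.zeros(2), std_errors=np.ones(2),
        p_values=np.ones(2), residuals=np.zeros(4), sigma2_ml=1.0,
        log_likelihood=lnl, model=model, n=4, k=2, y=y, X=X,
    )


class TestGlsFit:
    def test_closed_form_ols_example(self):
        fit = ols_fit([0.0, 2.0, 1.0],
                      np.column_stack([np.ones(3), [0.0, 1.0, 2.0]]))
        assert fit.coefficients[0] == pytest.approx(0.5)
        assert fit.coefficients[1] == pytest.approx(0.5)

    def test_identity_covariance_matches_ols_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(5, 30))
            k = int(rng.integers(1, 4))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, k))])
            y = rng.normal(size=n)
            fit = gls_fit(y, X, np.eye(n))
            ref = sm.OLS(y, X).fit()
            np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-10)
            np.testing.assert_allclose(fit.residuals, ref.resid, atol=1e-10)
            np.testing.assert_allclose(fit.p_values, ref.pvalues, atol=1e-10)
            # ML likelihood with C = I equals statsmodels' OLS loglik
            assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-8)

    def test_residual_orthogonality_under_tree_covariance(self):
        rng = np.random.default_rng(17)
        t = random_tree(rng, 12)
        C = phylo_covariance(t).matrix
        X = np.column_stack([np.ones(12), rng.normal(size=12)])
        y = rng.normal(size=12)
        fit = gls_fit(y, X, C, model=HIERARCHICAL)
        np.testing.assert_allclose(
            X.T @ np.linalg.solve(C, fit.residuals), 0.0, atol=1e-8
        )

    def test_covariance_rescaling_leaves_beta_and_p_unchanged(self):
        rng = np.random.default_rng(23)
        t = random_tree(rng, 10)
        C = phylo_covariance(t).matrix
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        y = rng.normal(size=10)
        f1 = gls_fit(y, X, C)
        f2 = gls_fit(y, X, 7.3 * C)
        np.testing.assert_allclose(f1.coefficients, f2.coefficients, atol=1e-8)
        np.testing.assert_allclose(f1.p_values, f2.p_values, atol=1e-8)
        assert f2.sigma2_ml == pytest.approx(f1.sigma2_ml / 7.3)

    def test_singular_covariance_raises(self):
        C = np.ones((4, 4))
        with pytest.raises(LinearAlgebraError):
            gls_fit(np.arange(4.0),
                    np.column_stack([np.ones(4), np.arange(4.0)]), C)

    def test_perfect_fit_raises_degenerate_likelihood(self):
        x = np.arange(5.0)
        with pytest.raises(DegenerateLikelihoodError):
            gls_fit(2.0 + 3.0 * x, np.column_stack([np.ones(5), x]), np.eye(5))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(DataError):
            gls_fit(np.arange(4.0), np.ones((3, 2)), np.eye(3))


class TestLrtCompare:
    def test_published_likelihood_pair_selects_hierarchical(self):
        choice = lrt_compare(make_fit(13.069, STAR),
                             make_fit(19.423, HIERARCHICAL))
        assert choice.lrt == pytest.approx(12.708)
        assert choice.lrt > choice.critical_value
        assert choice.selected == HIERARCHICAL

    def test_higher_star_likelihood_selects_star_when_significant(self):
        choice = lrt_compare(make_fit(20.0, STAR), make_fit(10.0, HIERARCHICAL))
        assert choice.selected == STAR

    def test_tie_prefers_hierarchical(self):
        choice = lrt_compare(make_fit(10.0, STAR), make_fit(10.0, HIERARCHICAL))
        assert choice.lrt == 0.0
        assert choice.selected == HIERARCHICAL

    def test_boundary_lrt_prefers_hierarchical(self):
        # LRT exactly at the critical value is not "larger than" it
        from phylodigit import chisq_quantile

        crit = chisq_quantile(0.05, 1)
        choice = lrt_compare(make_fit(0.0, STAR),
                             make_fit(crit / 2, HIERARCHICAL))
        assert choice.lrt == choice.critical_value
        assert choice.selected == HIERARCHICAL

    def test_mismatched_designs_raise(self):
        a = make_fit(1.0)
        b = make_fit(2.0, HIERARCHICAL)
        b.X = b.X + 1.0
        with pytest.raises(DataError):
            lrt_compare(a, b)


class TestRegressionGrid:
    @pytest.fixture()
    def small_problem(self):
        rng = np.random.default_rng(31)
        tree = random_tree(rng, 8)
        species = tree.tip_labels
        traits = pd.DataFrame(
            rng.normal(size=(8, 3)), index=species, columns=["t1", "t2", "t3"]
        )
        subs = rng.dirichlet(np.ones(5), size=8)
        substrates = pd.DataFrame(
            subs, index=species, columns=["sand", "rocks", "trunks",
                                          "ground", "perches"])
        return tree, traits, substrates

    def test_grid_shape_and_completeness(self, small_problem):
        tree, traits, substrates = small_problem
        grid = run_regression_grid(traits, substrates, tree)
        assert len(grid) == 3 * 5 * 2
        counts = grid.groupby(["trait", "substrate", "model"]).size()
        assert (counts == 1).all()

    def test_zero_variance_substrate_recorded_degenerate(self, small_problem):
        tree, traits, substrates = small_problem
        substrates = substrates.copy()
        substrates["rocks"] = 0.25
        grid = run_regression_grid(traits, substrates, tree)
        rocky = grid[grid.substrate == "rocks"]
        assert rocky.degenerate.all()
        assert grid[grid.substrate != "rocks"].degenerate.eq(False).all()

    def test_species_mismatch_raises(self, small_problem):
        tree, traits, substrates = small_problem
        with pytest.raises(Exception, match="keying"):
            run_regression_grid(traits.iloc[:-1], substrates, tree)

    def test_injected_effect_is_grid_minimum(self, small_problem):
        # one strong true association should dominate its trait's row
        rng = np.random.default_rng(77)
        tree, traits, substrates = small_problem
        traits = traits.copy()
        traits["t1"] = (
            5.0 * substrates["perches"] + 0.05 * rng.normal(size=8)
        )
        grid = run_regression_grid(traits, substrates, tree)
        t1 = grid[(grid.trait == "t1") & (grid.model == "star")]
        best = t1.loc[t1.p_value.idxmin(), "substrate"]
        assert best == "perches"


class TestNullCalibration:
    def test_pgls_slope_type_one_error_near_nominal(self, nee_tree,
                                                    species_dataset):
        """Brownian trait vs fixed perch index: ~5% false positives."""
        from phylodigit import simulate_bm

        C = phylo_covariance(nee_tree)
        species = nee_tree.tip_labels
        x = species_dataset.table.loc[species, "perches"].to_numpy()
        X = np.column_stack([np.ones(len(x)), x])
        rejections = 0
        n_rep = 500
        for s in range(n_rep):
            tips = simulate_bm(nee_tree, 1.0, 0.0, seed=40_000 + s)
            y = np.array([tips[sp] for sp in species])
            fit = gls_fit(y, X, C, model=HIERARCHICAL)
            rejections += fit.slope_p < 0.05
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.08
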