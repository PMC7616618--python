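import numpy as np
import pandas as pd
import pytest

from antpath.bpmm import (CHI2_PRIOR, FISHER_PRIOR, PhyloMixedModel,
                          convergence_diagnostics, marginal_r2_median,
                          phylo_heritability, pmcmc_compare, pool_across_trees,
                          posterior_mode_ci)
from antpath.simulate import simulate_yule


class TestPosteriorSummaries:
    def test_mode_and_hpd_for_standard_normal(self):
        x = np.random.default_rng(0).normal(size=100_000)
        mode, (lo, hi) = posterior_mode_ci(x)
        assert abs(mode) < 0.05
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_constant_samples(self):
        mode, ci = posterior_mode_ci(np.full(500, 3.25))
        assert mode == 3.25 and ci == (3.25, 3.25)

    def test_shift_equivariance(self):
        x = np.random.default_rng(1).normal(size=20_000)
        m0, _ = posterior_mode_ci(x)
        m1, _ = posterior_mode_ci(x + 7.0)
        assert m1 == pytest.approx(m0 + 7.0, abs=0.03)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            posterior_mode_ci(np.ones(10))


class TestHeritability:
    def test_arithmetic(self):
        h = phylo_heritability(np.full(200, 3.0), np.full(200, 1.0))
        assert h["mode"] == pytest.approx(75.0)

    def test_zero_phylogenetic_variance(self):
        h = phylo_heritability(np.zeros(200), np.ones(200))
        assert h["mode"] == pytest.approx(0.0)


class TestPMCMC:
    def test_one_sided_proportion(self):
        a = np.arange(1000, dtype=float)
        b = a.copy()
        b[:995] -= 1.0  # a > b in 995 of 1000 draws
        b[995:] += 1.0
        assert pmcmc_compare(a, b) == pytest.approx(0.005)

    def test_identical_chains_give_half(self):
        x = np.random.default_rng(2).normal(size=400)
        assert pmcmc_compare(x, x) == pytest.approx(0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pmcmc_compare(np.ones(5), np.ones(6))

    def test_null_behaviour_mostly_nonsignificant(self):
        rng = np.random.default_rng(3)
        ps = [pmcmc_compare(rng.normal(size=500), rng.normal(size=500))
              for _ in range(20)]
        assert np.mean(np.array(ps) > 0.05) > 0.6


class TestDiagnostics:
    def test_identical_chains_psrf_one(self):
        x = np.random.default_rng(4).normal(size=1000)
        d = convergence_diagnostics([x, x])
        assert d["psrf"] == pytest.approx(1.0, abs=0.05)

    def test_iid_ess_close_to_n(self):
        x = np.random.default_rng(5).normal(size=1000)
        d = convergence_diagnostics([x])
        assert d["ess"] == pytest.approx(1000, rel=0.25)
        assert d["psrf"] is None

    def test_ar1_ess_matches_closed_form(self):
        rho, n = 0.9, 8000
        rng = np.random.default_rng(6)
        x = np.zeros(n)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + rng.normal()
        d = convergence_diagnostics([x])
        expected = n * (1 - rho) / (1 + rho)
        assert d["ess"] == pytest.approx(expected, rel=0.4)
        assert d["lag1_autocorr"] == pytest.approx(rho, abs=0.05)


@pytest.fixture(scope="module")
def gaussian_fit():
    tree = simulate_yule(80, seed=8)
    cov = tree.covariance()
    A = cov.matrix / np.max(np.diag(cov.matrix))
    rng = np.random.default_rng(9)
    x = rng.multivariate_normal(np.zeros(80), A, method="cholesky")
    a = rng.multivariate_normal(np.zeros(80), 0.5 * A, method="cholesky")
    y = 0.8 + 0.4 * x + a + rng.normal(0, 0.7, 80)
    X = np.column_stack([np.ones(80), x])
    model = PhyloMixedModel(y, X, cov, exog_names=["(Intercept)", "x"])
    return model.fit(iterations=3000, burn_in=400, thinning=4, seed=1,
                     n_chains=2)


class TestGaussianModel:
    def test_star_covariance_reduces_to_ols(self):
        rng = np.random.default_rng(10)
        n = 150
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * x + rng.normal(0, 1.0, n)
        X = np.column_stack([np.ones(n), x])
        model = PhyloMixedModel(y, X, np.eye(n), exog_names=["b0", "b1"])
        res = model.fit(iterations=3000, burn_in=400, thinning=4, seed=2)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert res.draws("b1").mean() == pytest.approx(ols[1], abs=0.08)

    def test_summary_and_diagnostics_shape(self, gaussian_fit):
        s = gaussian_fit.summary()
        assert list(s["parameter"]) == ["(Intercept)", "x", "V_A", "V_R"]
        d = gaussian_fit.diagnostics()
        assert (d["ess"] > 0).all()
        assert d["psrf"].notna().all()

    def test_heritability_between_zero_and_hundred(self, gaussian_fit):
        h = gaussian_fit.heritability()
        assert 0 <= h["ci"][0] <= h["mode"] <= h["ci"][1] <= 100

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=30)
        X = np.ones((30, 1))
        cov = simulate_yule(30, seed=12).covariance()
        r1 = PhyloMixedModel(y, X, cov).fit(iterations=500, burn_in=100,
                                            thinning=2, seed=5)
        r2 = PhyloMixedModel(y, X, cov).fit(iterations=500, burn_in=100,
                                            thinning=2, seed=5)
        assert np.array_equal(r1.draws("V_A"), r2.draws("V_A"))

    def test_parameter_expanded_priors_run(self):
        rng = np.random.default_rng(13)
        cov = simulate_yule(40, seed=14).covariance()
        A = cov.matrix / np.max(np.diag(cov.matrix))
        y = rng.multivariate_normal(np.zeros(40), A + 0.3 * np.eye(40))
        X = np.ones((40, 1))
        for prior in (FISHER_PRIOR, CHI2_PRIOR):
            res = PhyloMixedModel(y, X, cov, prior=prior).fit(
                iterations=800, burn_in=200, thinning=2, seed=3)
            assert np.all(res.draws("V_A") >= 0)


class TestMarginalR2:
    def test_zero_slopes_give_zero(self):
        rng = np.random.default_rng(15)
        cov = simulate_yule(60, seed=16).covariance()
        y = rng.normal(size=60)
        X = np.column_stack([np.ones(60), rng.normal(size=60)])
        res = PhyloMixedModel(y, X, cov, exog_names=["b0", "x"]).fit(
            iterations=2000, burn_in=300, thinning=3, seed=4)
        assert res.marginal_r2()["median"] < 0.1

    def test_pure_fixed_effect_limit(self):
        rng = np.random.default_rng(17)
        cov = simulate_yule(60, seed=18).covariance()
        x = rng.normal(size=60)
        y = 2.0 * x + rng.normal(0, 0.02, 60)
        X = np.column_stack([np.ones(60), x])
        res = PhyloMixedModel(y, X, cov, exog_names=["b0", "x"]).fit(
            iterations=2000, burn_in=300, thinning=3, seed=5)
        assert res.marginal_r2()["median"] > 0.9

    def test_poisson_family_not_provided(self):
        cov = simulate_yule(30, seed=19).covariance()
        y = np.random.default_rng(20).poisson(2.0, 30)
        res = PhyloMixedModel(y, np.ones((30, 1)), cov,
                              family="poisson_log").fit(
            iterations=500, burn_in=100, thinning=2, seed=6)
        with pytest.raises(ValueError):
            res.marginal_r2()


class TestPooling:
    def _fit(self, seed, tree_index):
        cov = simulate_yule(25, seed=21).covariance()
        y = np.random.default_rng(seed).normal(size=25)
        return PhyloMixedModel(y, np.ones((25, 1)), cov).fit(
            iterations=600, burn_in=100, thinning=2, seed=seed,
            tree_index=tree_index)

    def test_pooled_length_is_sum(self):
        r1, r2 = self._fit(1, 0), self._fit(2, 1)
        pooled = pool_across_trees([r1, r2])
        assert pooled.n_draws == r1.n_draws + r2.n_draws
        assert set(pooled.provenance) == {0, 1}

    def test_identical_chains_pool_to_same_summary(self):
        r1 = self._fit(3, 0)
        pooled = pool_across_trees([r1, r1])
        s1 = r1.summary().set_index("parameter")
        sp = pooled.summary().set_index("parameter")
        assert sp.loc["V_A", "post_mode"] == pytest.approx(
            s1.loc["V_A", "post_mode"], rel=0.2, abs=0.05)

    def test_mismatched_parameters_rejected(self):
        cov = simulate_yule(25, seed=21).covariance()
        y = np.random.default_rng(4).normal(size=25)
        ra = PhyloMixedModel(y, np.ones((25, 1)), cov, exog_names=["a"]).fit(
            iterations=300, burn_in=50, thinning=2, seed=1)
        rb = PhyloMixedModel(y, np.column_stack([np.ones(25), y]), cov,
                             exog_names=["a", "b"]).fit(
            iterations=300, burn_in=50, thinning=2, seed=1)
        with pytest.raises(ValueError):
            pool_across_trees([ra, rb])

    def test_r2_median_across_trees(self):
        r1, r2 = self._fit(5, 0), self._fit(6, 1)
        out = marginal_r2_median([r1, r2])
        assert 0 <= out["median_of_tree_medians"] <= 1
        assert len(out["per_tree"]) == 2


class TestFromDataFrame:
    def _data(self, n=40, seed=22):
        tree = simulate_yule(n, seed=seed)
        rng = np.random.default_rng(seed)
        return tree, pd.DataFrame({
            "species": tree.tip_labels,
            "y": rng.normal(size=n),
            "x": rng.normal(size=n),
            "grp": rng.choice(["u", "v", "w"], n),
        })

    def test_formula_with_categorical_no_intercept(self):
        tree, data = self._data()
        m = PhyloMixedModel.from_dataframe("y ~ 0 + grp", data, tree)
        assert m.exog_names == ["grp[u]", "grp[v]", "grp[w]"]
        assert m.X.sum() == pytest.approx(len(data))

    def test_unmatched_species_dropped(self):
        tree, data = self._data()
        data.loc[0, "species"] = "not_a_tip"
        m = PhyloMixedModel.from_dataframe("y ~ x", data, tree)
        assert len(m.y) == len(data) - 1

    def test_unknown_term_rejected(self):
        tree, data = self._data()
        with pytest.raises(KeyError):
            PhyloMixedModel.from_dataframe("y ~ nope", data, tree)
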