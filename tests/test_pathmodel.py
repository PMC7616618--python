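import numpy as np
import pandas as pd
import pytest

from antpath.pathmodel import (PGLS, CausalDAG, PathFitResult, PhyloLogistic,
                               average_paths, basis_set, candidate_models,
                               cicc, dsep_test, rank_models,
                               run_candidate_set)
from antpath.simulate import (generate_species_table, simulate_continuous,
                              simulate_yule)


class TestDAGs:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            CausalDAG("cyclic", [("a", "b"), ("b", "a")])

    def test_edge_list_parser(self):
        dag = CausalDAG.from_edge_list("m", "a -> b\n# comment\nb -> c\n")
        assert dag.edges == [("a", "b"), ("b", "c")]

    def test_candidate_set_shares_mating_edges(self):
        models = candidate_models()
        for dag in models.values():
            assert ("queen_number", "mating_frequency") in dag.edges
            assert ("colony_size", "mating_frequency") in dag.edges
        assert ("colony_size", "castes") in models["model_1"].edges
        assert ("castes", "colony_size") in models["model_2"].edges
        assert ("mating_frequency", "castes") in models["model_3"].edges
        assert ("mating_frequency", "castes") in models["model_4"].edges


class TestBasisSet:
    def test_chain_yields_single_claim(self):
        dag = CausalDAG("chain", [("a", "b"), ("b", "c")])
        claims = basis_set(dag)
        assert len(claims) == 1
        cl = claims[0]
        assert {cl.x, cl.y} == {"a", "c"}
        assert cl.conditioning == ("b",)
        assert cl.response == "c"

    def test_complete_dag_is_empty(self):
        dag = CausalDAG("full", [("a", "b"), ("a", "c"), ("b", "c")])
        assert basis_set(dag) == []

    def test_model1_claims_enumerated(self):
        # hand enumeration for the size->castes hypothesis
        dag = candidate_models()["model_1"]
        claims = {(c.x, c.y): c.conditioning for c in basis_set(dag)}
        assert claims == {
            ("castes", "mating_frequency"): ("colony_size", "queen_number"),
            ("castes", "queen_number"): ("colony_size",),
            ("colony_size", "queen_number"): (),
        }

    def test_deterministic_ordering(self):
        dag = candidate_models()["model_3"]
        assert basis_set(dag) == basis_set(dag)


class TestPGLS:
    def test_lambda_zero_equals_ols(self):
        rng = np.random.default_rng(1)
        tree = simulate_yule(60, seed=2)
        x = rng.normal(size=60)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.5, 60)
        X = np.column_stack([np.ones(60), x])
        fit = PGLS(y, X, tree.covariance()).fit(lam=0.0)
        import statsmodels.api as sm

        ols = sm.OLS(y, X).fit()
        assert np.allclose(fit.params, ols.params, atol=1e-8)
        assert np.allclose(fit.bse, ols.bse, atol=1e-8)
        assert np.allclose(fit.pvalues, ols.pvalues, atol=1e-8)

    def test_brownian_slope_recovery(self):
        hits = 0
        for seed in range(8):
            tree = simulate_yule(120, seed=100 + seed)
            data = simulate_continuous(
                tree, {("x", "y"): 0.5}, sigma2=1.0, lam=1.0, seed=seed)
            X = np.column_stack([np.ones(len(data)), data["x"]])
            fit = PGLS(data["y"], X, tree.covariance()).fit()
            lo, hi = fit.conf_int()[1]
            hits += lo <= 0.5 <= hi
        assert hits >= 6

    def test_lambda_estimated_high_for_brownian_data(self):
        tree = simulate_yule(150, seed=7)
        data = simulate_continuous(tree, {}, traits=["y"], sigma2=1.0,
                                   lam=1.0, seed=8)
        fit = PGLS(data["y"], np.ones((150, 1)), tree.covariance()).fit()
        assert fit.lam > 0.7

    def test_duplicated_predictor_rejected(self):
        tree = simulate_yule(20, seed=9)
        x = np.random.default_rng(3).normal(size=20)
        X = np.column_stack([np.ones(20), x, x])
        with pytest.raises(np.linalg.LinAlgError):
            PGLS(x, X, tree.covariance())


class TestPhyloLogistic:
    def test_reduces_to_ordinary_logistic_without_signal(self):
        rng = np.random.default_rng(4)
        n = 300
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.3 + 0.8 * x)))
        y = (rng.uniform(size=n) < p).astype(float)
        X = np.column_stack([np.ones(n), x])
        fit = PhyloLogistic(y, X, np.eye(n)).fit()
        import statsmodels.api as sm

        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.allclose(fit.params, glm.params, atol=0.3)
        assert fit.params[1] > 0 and fit.pvalues[1] < 0.01

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError):
            PhyloLogistic(np.ones(20), np.ones((20, 1)), np.eye(20))

    def test_separation_flagged(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(float)
        X = np.column_stack([np.ones(40), x])
        fit = PhyloLogistic(y, X, np.eye(40)).fit()
        assert fit.separation
        assert np.all(np.isfinite(fit.bse))

    def test_threshold_model_slope_recovered(self):
        hits = 0
        for seed in range(6):
            tree = simulate_yule(150, seed=200 + seed)
            data = simulate_continuous(tree, {}, traits=["x"], sigma2=1.0,
                                       lam=1.0, seed=seed)
            x = data["x"].to_numpy()
            rng = np.random.default_rng(seed)
            y = (rng.uniform(size=150) <
                 1 / (1 + np.exp(-1.5 * x))).astype(float)
            if y.std() == 0:
                continue
            X = np.column_stack([np.ones(150), x])
            fit = PhyloLogistic(y, X, tree.covariance()).fit()
            hits += (fit.params[1] > 0) and (fit.pvalues[1] < 0.05)
        assert hits >= 4


class TestFisherC:
    def test_all_pvalues_one_gives_zero(self):
        dag = CausalDAG("full", [("a", "b"), ("a", "c"), ("b", "c")])
        C, p, k, _ = dsep_test(dag, pd.DataFrame({"a": [], "b": [], "c": []}),
                               np.eye(0) if False else _tiny_cov(), None)
        assert C == 0.0 and p == 1.0 and k == 0

    def test_known_chi_square_example(self):
        # p-values (0.5, 0.5): C = -2 (ln .5 + ln .5) = 2.7726, df = 4
        pvals = [0.5, 0.5]
        C = -2 * np.sum(np.log(pvals))
        from scipy.stats import chi2

        assert C == pytest.approx(2.772589, abs=1e-6)
        assert chi2.sf(C, 4) == pytest.approx(0.5966, abs=1e-4)
        # survival closed form for chi2 with 4 df: e^(-x/2) (1 + x/2)
        assert chi2.sf(C, 4) == pytest.approx(
            np.exp(-C / 2) * (1 + C / 2), abs=1e-12)


def _tiny_cov():
    from antpath.treeio import PhyloCovariance

    return PhyloCovariance(taxa=[], matrix=np.zeros((0, 0)))


class TestCICcAndWeights:
    @pytest.mark.parametrize("C, q, n, expected", [
        (2.0, 3, 10, 12.0),
        (0.0, 0, 50, 0.0),
    ])
    def test_formula(self, C, q, n, expected):
        assert cicc(C, q, n) == pytest.approx(expected, abs=1e-12)

    def test_large_n_limit(self):
        assert cicc(5.0, 3, 10**7) == pytest.approx(11.0, abs=1e-4)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            cicc(1.0, 9, 10)

    def _fits(self, ciccs):
        return [PathFitResult(name=f"m{i}", C=c, p_C=0.5, k=1, q=1, n=50,
                              CICc=c) for i, c in enumerate(ciccs)]

    def test_equal_scores_split_weight(self):
        ranking = rank_models(self._fits([10.0, 10.0]))
        assert np.allclose(ranking["omega"], 0.5)

    def test_delta_two_weighting(self):
        ranking = rank_models(self._fits([10.0, 12.0])).set_index("model")
        assert ranking.loc["m0", "omega"] == pytest.approx(0.7311, abs=1e-4)
        assert ranking.loc["m1", "omega"] == pytest.approx(0.2689, abs=1e-4)

    def test_weights_sum_to_one_and_shift_invariant(self):
        r1 = rank_models(self._fits([3.0, 4.5, 9.0]))
        r2 = rank_models(self._fits([103.0, 104.5, 109.0]))
        assert r1["omega"].sum() == pytest.approx(1.0)
        assert np.allclose(np.sort(r1["omega"]), np.sort(r2["omega"]))


class TestAveraging:
    def _fit(self, name, cicc_val, edges):
        coef = pd.DataFrame(
            [{"edge": e, "beta": b, "se": s} for e, (b, s) in edges.items()]
        ).set_index("edge") if edges else pd.DataFrame(columns=["beta", "se"])
        return PathFitResult(name=name, C=0, p_C=1, k=0, q=1, n=50,
                             CICc=cicc_val, coefficients=coef)

    def test_single_supported_model_identity(self):
        fits = [self._fit("a", 0.0, {"x -> y": (0.8, 0.1)}),
                self._fit("b", 9.0, {"x -> y": (0.1, 0.1)})]
        rank_models(fits)
        avg = average_paths(fits)
        assert avg.loc["x -> y", "beta"] == pytest.approx(0.8)

    def test_absent_path_contributes_zero(self):
        fits = [self._fit("a", 0.0, {"x -> y": (1.0, 0.2)}),
                self._fit("b", 0.81093022, {})]  # omega ratio 0.6 / 0.4
        rank_models(fits)
        avg = average_paths(fits)
        assert avg.loc["x -> y", "beta"] == pytest.approx(0.6, abs=1e-6)

    def test_path_absent_everywhere_is_exactly_zero(self):
        fits = [self._fit("a", 0.0, {}), self._fit("b", 0.5, {})]
        rank_models(fits)
        assert average_paths(fits).empty


class TestRunCandidateSet:
    @pytest.fixture(scope="class")
    def dataset(self):
        return generate_species_table("size_complexity_true", 120, seed=33)

    def test_ranking_is_complete_and_weighted(self, dataset):
        res = run_candidate_set(dataset.analysis_table, dataset.tree,
                                response_mode="castes_binary")
        assert len(res["ranking"]) == 4
        assert res["ranking"]["omega"].sum() == pytest.approx(1.0)
        assert (res["ranking"]["CICc"] >= res["ranking"]["C"] - 1e-9).all()

    def test_monomorphic_subset_identity(self, dataset):
        table = dataset.analysis_table.copy()
        table["castes"] = 1  # all monomorphic: the two modes coincide
        a = run_candidate_set(table, dataset.tree, response_mode="worker_cv")
        b = run_candidate_set(table, dataset.tree,
                              response_mode="worker_cv_monomorphic_only")
        assert np.allclose(a["ranking"]["CICc"], b["ranking"]["CICc"])

    def test_too_few_complete_cases_rejected(self, dataset):
        table = dataset.analysis_table.head(5)
        with pytest.raises(ValueError):
            run_candidate_set(table, dataset.tree)
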