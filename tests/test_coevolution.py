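import numpy as np
import pytest

from antpath.coevolution import (DEP_RATE_NAMES, IND_RATE_NAMES,
                                 DiscretePairCoevolution, RateModel, RJChain,
                                 bayes_factor, build_generator,
                                 pair_tip_partials, simulate_pair_ctmc)
from antpath.simulate import simulate_yule
from antpath.treeio import Phylogeny


class TestGenerator:
    def test_rows_sum_to_zero_and_no_double_transitions(self, rng):
        Q = build_generator("dependent", rng.uniform(0.1, 2.0, 8))
        assert np.allclose(Q.sum(axis=1), 0.0)
        # simultaneous changes of both traits: (0,0)<->(1,1), (0,1)<->(1,0)
        assert Q[0, 3] == Q[3, 0] == Q[1, 2] == Q[2, 1] == 0.0

    def test_independent_is_constrained_dependent(self, rng):
        r = rng.uniform(0.1, 2.0, 4)
        Qi = build_generator("independent", r)
        g1, l1, g2, l2 = r
        Qd = build_generator("dependent", [g1, g1, l1, l1, g2, g2, l2, l2])
        assert np.allclose(Qi, Qd)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            build_generator("independent", [-0.1, 1, 1, 1])

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            RateModel("independent", np.ones(8))


class TestLikelihoodAndML:
    def test_all_rates_zero_two_tips(self):
        # no change possible: the root must equal the tips' shared state
        tree = Phylogeny.from_newick("(A:1,B:1):0;")
        model = DiscretePairCoevolution(
            tree, {"A": (0, 0), "B": (0, 0)})
        ll = model.loglik(RateModel("independent", np.zeros(4)))
        assert ll == pytest.approx(np.log(0.25), abs=1e-12)

    def test_dependent_nests_independent(self):
        tree = simulate_yule(60, seed=3)
        truth = RateModel("independent", np.array([0.6, 0.6, 0.6, 0.6]) / tree.height())
        tips, _ = simulate_pair_ctmc(tree, truth, seed=4)
        model = DiscretePairCoevolution(tree, tips)
        fi = model.fit_ml("independent", seed=0)
        fd = model.fit_ml("dependent", seed=0)
        assert fd.loglik >= fi.loglik - 1e-6

    def test_constant_trait_flagged(self):
        tree = simulate_yule(20, seed=5)
        tips = {lab: (0, i % 2) for i, lab in enumerate(tree.tip_labels)}
        model = DiscretePairCoevolution(tree, tips)
        fit = model.fit_ml("independent", seed=0)
        assert fit.at_boundary

    def test_zero_rate_recovered_from_simulation(self):
        # hard-zero caste gain in the small class leaves a near-zero ML rate
        tree = simulate_yule(150, seed=11).scale_branches(1.0)
        h = tree.height()
        truth = RateModel("dependent",
                          np.array([0.8, 0.8, 0.8, 0.8, 0.0, 2.0, 0.4, 0.4]) / h)
        tips, _ = simulate_pair_ctmc(tree, truth, seed=12, root_state=(0, 0))
        model = DiscretePairCoevolution(tree, tips)
        fit = model.fit_ml("dependent", seed=1)
        i = DEP_RATE_NAMES.index("gain2|1=0")
        others = [fit.rates[DEP_RATE_NAMES.index(n)]
                  for n in ("gain1|2=0", "gain2|1=1")]
        assert fit.rates[i] < 0.05 * max(others)

    def test_missing_trait_enters_ambiguously(self, rng):
        tree = Phylogeny.from_newick("((A:1,B:1):1,C:2):0;")
        Q = build_generator("dependent", rng.uniform(0.2, 1.5, 8))
        full = DiscretePairCoevolution(
            tree, {"A": (0, 0), "B": (1, 1), "C": (0, None)})
        parts = []
        for s in (0, 1):
            m = DiscretePairCoevolution(
                tree, {"A": (0, 0), "B": (1, 1), "C": (0, s)})
            parts.append(m.loglik(RateModel("dependent", rng.uniform(0.2, 1.5, 8))))
        # compare using one shared rate vector
        r = rng.uniform(0.2, 1.5, 8)
        total = full.loglik(RateModel("dependent", r))
        parts = [DiscretePairCoevolution(tree, {"A": (0, 0), "B": (1, 1), "C": (0, s)}
                                         ).loglik(RateModel("dependent", r))
                 for s in (0, 1)]
        assert total == pytest.approx(np.log(np.exp(parts[0]) + np.exp(parts[1])),
                                      abs=1e-9)


class TestBayesFactor:
    @pytest.mark.parametrize("delta, bf, label", [
        (1.0, 2.0, "positive"),
        (0.0, 0.0, "no support"),
        (10.415, 20.83, "very strong"),
        (3.0, 6.0, "strong"),
    ])
    def test_formula_and_labels(self, delta, bf, label):
        res = bayes_factor(delta, 0.0)
        assert res.bf == pytest.approx(bf, abs=1e-9)
        assert res.label == label

    def test_infinite_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor(np.inf, 0.0)


class TestRJChain:
    def _chain(self, rates):
        return RJChain(kind="independent", rates=np.asarray(rates, float),
                       hyper=np.ones((len(rates), 1)),
                       loglik=np.zeros(len(rates)),
                       rate_names=IND_RATE_NAMES, iterations=0, burn_in=0,
                       thinning=1, seed=0)

    def test_zero_rate_proportion(self):
        rates = np.ones((100, 4))
        rates[:60, 2] = 0.0
        chain = self._chain(rates)
        assert chain.zero_rate_proportion(2) == pytest.approx(0.6)
        assert chain.zero_rate_proportion("gain1") == 0.0
        rates[:, 3] = 0.0
        assert self._chain(rates).zero_rate_proportion("loss2") == 1.0

    def test_bad_index(self):
        with pytest.raises(IndexError):
            self._chain(np.ones((10, 4))).zero_rate_proportion(7)

    def test_empty_chain(self):
        with pytest.raises(ValueError):
            self._chain(np.ones((0, 4))).zero_rate_proportion(0)


class TestSamplers:
    def test_rjmcmc_reproducible_and_shaped(self):
        tree = simulate_yule(40, seed=21).scale_branches(0.05 / 4)
        truth = RateModel("independent", np.array([8.0, 8.0, 6.0, 6.0]))
        tips, _ = simulate_pair_ctmc(tree, truth, seed=22)
        model = DiscretePairCoevolution(tree, tips)
        c1 = model.rjmcmc("independent", iterations=300, burn_in=50,
                          thinning=5, seed=7)
        c2 = model.rjmcmc("independent", iterations=300, burn_in=50,
                          thinning=5, seed=7)
        assert c1.rates.shape == (50, 4)
        assert np.array_equal(c1.rates, c2.rates)
        assert np.all(c1.rates >= 0)

    def test_two_chain_psrf_near_one(self):
        tree = simulate_yule(60, seed=31)
        tree = tree.scale_branches(0.05 / tree.height())
        truth = RateModel("independent", np.array([12.0, 12.0, 10.0, 10.0]))
        tips, _ = simulate_pair_ctmc(tree, truth, seed=32)
        model = DiscretePairCoevolution(tree, tips)
        lls = []
        for seed in (1, 2):
            c = model.rjmcmc("independent", iterations=1200, burn_in=300,
                             thinning=2, seed=seed)
            lls.append(c.loglik)
        import arviz as az

        psrf = float(az.rhat(np.asarray(lls)))
        assert psrf < 1.2

    def test_tree_resampling_mode_records_index(self):
        from antpath.treeio import TreeSample

        base = simulate_yule(30, seed=41)
        sample = TreeSample([base, base.scale_branches(0.9)])
        truth = RateModel("independent", np.full(4, 1.0) / base.height())
        tips, _ = simulate_pair_ctmc(base, truth, seed=42)
        model = DiscretePairCoevolution(base, tips)
        chain = model.rjmcmc("independent", iterations=200, burn_in=40,
                             thinning=2, seed=3, trees=sample)
        assert chain.tree_index is not None
        assert set(np.unique(chain.tree_index)) <= {0, 1}

    def test_stepping_stone_seed_stability(self):
        tree = simulate_yule(50, seed=51)
        tree = tree.scale_branches(0.05 / tree.height())
        truth = RateModel("independent", np.array([10.0, 10.0, 8.0, 8.0]))
        tips, _ = simulate_pair_ctmc(tree, truth, seed=52)
        model = DiscretePairCoevolution(tree, tips)
        lmls = [model.stepping_stone("independent", n_stones=12,
                                     iters_per_stone=60, burn_per_stone=20,
                                     seed=s).log_ml for s in (1, 2)]
        assert abs(lmls[0] - lmls[1]) < 2.0


class TestPairSimulation:
    def test_all_rates_zero(self, rng):
        tree = simulate_yule(10, seed=61)
        tips, sim = simulate_pair_ctmc(
            tree, RateModel("dependent", np.zeros(8)), seed=1, root_state=(1, 0))
        assert all(v == (1, 0) for v in tips.values())

    def test_hard_zero_gain_never_fires_in_forbidden_state(self):
        tree = simulate_yule(200, seed=71)
        h = tree.height()
        rates = np.array([0.8, 0.8, 0.8, 0.8, 0.0, 2.0, 0.4, 0.4]) / h
        tips, sim = simulate_pair_ctmc(
            tree, RateModel("dependent", rates), seed=2, root_state=(0, 0))
        # no event may move (0,0) -> (0,1): trait2 gained while trait1 small
        assert not any(s_from == 0 and s_to == 1 for _, _, s_from, s_to in sim.events)

    def test_partials_require_full_coverage(self):
        tree = Phylogeny.from_newick("(A:1,B:1):0;")
        with pytest.raises(KeyError):
            pair_tip_partials(tree, {"A": (0, 0)})
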