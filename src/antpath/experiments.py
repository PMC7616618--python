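"""Recovery and calibration experiments validating the whole pipeline.

Each function simulates data with known ground truth at desk scale
(100-300-tip trees, test-scale chains), runs the corresponding analysis
stage, and reports how often the truth is recovered.  The experiment
definitions double as the package's acceptance checks; seeds make every
run reproducible.
"""

from __future__ import annotations

import numpy as np

from . import markov
from .ancestral import (HiddenRateModel, ancestral_value_regression,
                        classify_nodes)
from .bpmm import PhyloMixedModel
from .coevolution import (DiscretePairCoevolution, RateModel, bayes_factor,
                          simulate_pair_ctmc)
from .pathmodel import candidate_models, dsep_test, run_candidate_set
from .simulate import (generate_species_table, simulate_bm_on_nodes,
                       simulate_continuous, simulate_dependent_binary,
                       simulate_yule)
from .ss import SteppingStoneModel, stepping_stone_logml
from .treeio import Phylogeny

__all__ = [
    "pruning_oracle",
    "BetaBernoulliModel",
    "stepping_stone_toy",
    "dependent_recovery",
    "independence_calibration",
    "path_structure_recovery",
    "dsep_type1_calibration",
    "bpmm_gaussian_recovery",
    "bpmm_poisson_sign_recovery",
    "asr_contrast_recovery",
]

# generating rates for the correlated-evolution regime, per unit tree height:
# trait1 = colony-size class (gain/loss), trait2 = multiple castes with the
# hard-zero gain in small colonies (see docs/methods.md)
_DEP_TRUTH = np.array([0.75, 0.75, 0.75, 0.75, 0.0, 2.0, 0.4, 0.4])
_IND_TRUTH = np.array([0.75, 0.75, 0.5, 0.5])

_SS_SETTINGS = dict(n_stones=24, iters_per_stone=100, burn_per_stone=40)
_RJ_SETTINGS = dict(iterations=3_000, burn_in=500, thinning=2)


def _random_tree(rng: np.random.Generator, n_tips: int) -> Phylogeny:
    return simulate_yule(n_tips, seed=int(rng.integers(2**31)))


def pruning_oracle(n_cases: int = 100, seed: int = 0, max_tips: int = 5) -> dict:
    """Pruning likelihood vs brute-force enumeration on tiny trees."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        n = int(rng.integers(2, max_tips + 1))
        tree = _random_tree(rng, n)
        Q = rng.uniform(0.0, 3.0, (4, 4))
        Q[rng.uniform(size=(4, 4)) < 0.3] = 0.0
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        partials = np.zeros((n, 4))
        partials[np.arange(n), rng.integers(0, 4, n)] = 1.0
        # occasionally make a tip ambiguous
        if rng.uniform() < 0.3:
            partials[int(rng.integers(n))] = 1.0
        l_prune = markov.PruningEngine(tree, partials).loglik(Q)
        l_enum = markov.enumeration_loglik(tree, Q, partials)
        if np.isfinite(l_prune) or np.isfinite(l_enum):
            worst = max(worst, abs(l_prune - l_enum))
    return {"max_abs_error": worst, "n_cases": n_cases}


class BetaBernoulliModel(SteppingStoneModel):
    """Conjugate toy with a closed-form marginal likelihood.

    ``k`` successes of ``n`` Bernoulli trials, uniform (Beta(1,1)) prior on
    the success probability: the marginal likelihood is Beta(1+k, 1+n-k).
    """

    def __init__(self, k: int, n: int):
        self.k, self.n = k, n

    def initial_state(self, rng):
        return float(rng.uniform())

    def log_prior(self, theta):
        return 0.0 if 0.0 < theta < 1.0 else -np.inf

    def log_lik(self, theta):
        return self.k * np.log(theta) + (self.n - self.k) * np.log1p(-theta)

    @property
    def proposals(self):
        def rw(theta, rng):
            logit = np.log(theta / (1 - theta)) + rng.normal(0.0, 0.8)
            new = 1.0 / (1.0 + np.exp(-logit))
            # Jacobian of the logit random walk
            log_h = (np.log(new) + np.log1p(-new)
                     - np.log(theta) - np.log1p(-theta))
            return new, float(log_h)

        def redraw(theta, rng):
            return float(rng.uniform()), 0.0

        return [rw, redraw]

    def exact_log_ml(self) -> float:
        from scipy.special import betaln

        return float(betaln(1 + self.k, 1 + self.n - self.k) - betaln(1, 1))


def stepping_stone_toy(n_seeds: int = 10, seed0: int = 0,
                       k: int = 7, n: int = 20) -> dict:
    """Stepping-stone error against the Beta-Bernoulli closed form."""
    model = BetaBernoulliModel(k, n)
    exact = model.exact_log_ml()
    errors = []
    for s in range(n_seeds):
        est = stepping_stone_logml(model, n_stones=32, iters_per_stone=1_000,
                                   burn_per_stone=200, seed=seed0 + s)
        errors.append(abs(est.log_ml - exact))
    return {"max_abs_error": float(max(errors)), "errors": errors,
            "exact_log_ml": exact, "n_seeds": n_seeds}


def _pair_experiment(truth: RateModel, n_tips: int, rep_seed: int) -> dict:
    """One replicate: simulate a pair of traits, compare models.

    Trees are rescaled to height 0.05 before analysis so that rates on the
    analysis scale fall inside the bulk of the uniform(0, 100) hyper-prior
    — the branch-scaling device used with rate models to keep transition
    rates away from hard-to-search small values.
    """
    rng = np.random.default_rng(rep_seed)
    for attempt in range(8):
        tree = _random_tree(rng, n_tips)
        tree = tree.scale_branches(0.05 / tree.height())
        scaled = RateModel(truth.kind, truth.rates / 0.05)
        tips, _ = simulate_pair_ctmc(
            tree, scaled, seed=int(rng.integers(2**31)), root_state=(0, 0))
        arr = np.array([v for v in tips.values()])
        if 0.05 < arr[:, 0].mean() < 0.95 and 0.05 < arr[:, 1].mean() < 0.95:
            break
    model = DiscretePairCoevolution(tree, tips)
    s_dep = model.stepping_stone("dependent", seed=int(rng.integers(2**31)),
                                 **_SS_SETTINGS)
    s_ind = model.stepping_stone("independent", seed=int(rng.integers(2**31)),
                                 **_SS_SETTINGS)
    bf = bayes_factor(s_dep.log_ml, s_ind.log_ml)
    return {"model": model, "bf": bf.bf, "rng": rng}


def dependent_recovery(n_reps: int = 20, n_tips: int = 200, seed: int = 0) -> dict:
    """Detecting the hard-zero caste-gain rate in small colonies.

    Data are simulated under the dependent model in which multiple castes
    can only be gained in the large-colony class; success means Bayes
    factor > 2 for the dependent model and posterior zero-proportion > 0.5
    for the true-zero rate.
    """
    truth = RateModel("dependent", _DEP_TRUTH)
    bf_hits = zero_hits = both = 0
    bfs, zps = [], []
    for rep in range(n_reps):
        out = _pair_experiment(truth, n_tips, seed * 100_003 + rep)
        chain = out["model"].rjmcmc("dependent",
                                    seed=int(out["rng"].integers(2**31)),
                                    **_RJ_SETTINGS)
        zp = chain.zero_rate_proportion("gain2|1=0")
        bfs.append(out["bf"])
        zps.append(zp)
        bf_hits += out["bf"] > 2
        zero_hits += zp > 0.5
        both += (out["bf"] > 2) and (zp > 0.5)
    return {"n_reps": n_reps, "bf_gt2": bf_hits, "zero_gt_half": zero_hits,
            "both": both, "bayes_factors": bfs, "zero_proportions": zps}


def independence_calibration(n_reps: int = 20, n_tips: int = 200,
                             seed: int = 0) -> dict:
    """Bayes factors under truly independent evolution should stay <= 2."""
    truth = RateModel("independent", _IND_TRUTH)
    hits = 0
    bfs = []
    for rep in range(n_reps):
        out = _pair_experiment(truth, n_tips, seed * 100_019 + rep)
        bfs.append(out["bf"])
        hits += out["bf"] <= 2
    return {"n_reps": n_reps, "bf_le2": hits, "bayes_factors": bfs}


def path_structure_recovery(n_reps: int = 20, n_tips: int = 300,
                            seed: int = 0) -> dict:
    """Top-ranked causal model on size-complexity-true synthetic studies."""
    tops = []
    for rep in range(n_reps):
        ds = generate_species_table("size_complexity_true", n_tips,
                                    seed=seed * 100_043 + rep)
        res = run_candidate_set(ds.analysis_table, ds.tree,
                                response_mode="castes_binary")
        tops.append(res["ranking"].iloc[0]["model"])
    frac = float(np.mean([t == "model_1" for t in tops]))
    return {"n_reps": n_reps, "model1_top": int(sum(t == "model_1" for t in tops)),
            "model1_top_fraction": frac, "top_models": tops}


def dsep_type1_calibration(n_reps: int = 100, n_tips: int = 150,
                           seed: int = 0, alpha: float = 0.05) -> dict:
    """Rejection rate of the true DAG by the d-sep test.

    Continuous (worker-size-variation) response mode: data are linear
    Gaussian under model 1, so Fisher's C is chi-square calibrated and the
    type-I rate should sit near alpha.
    """
    import pandas as pd

    dag = candidate_models(complexity="complexity")["model_1"]
    rejections = 0
    pvals = []
    rng = np.random.default_rng(seed)
    for rep in range(n_reps):
        tree = _random_tree(rng, n_tips)
        effects = {("colony_size", "complexity"): 0.5,
                   ("colony_size", "mating_frequency"): 0.4,
                   ("queen_number", "mating_frequency"): -0.3}
        data = simulate_continuous(tree, effects,
                                   traits=["complexity", "colony_size",
                                           "mating_frequency", "queen_number"],
                                   sigma2=1.0, lam=1.0,
                                   seed=int(rng.integers(2**31)))
        work = data.reset_index()
        for c in ["complexity", "colony_size", "mating_frequency", "queen_number"]:
            v = work[c].to_numpy()
            work[c] = (v - v.mean()) / v.std(ddof=1)
        cov = tree.covariance()
        order = {t: i for i, t in enumerate(cov.taxa)}
        work = work.iloc[np.argsort([order[s] for s in work["species"]])]
        work = work.reset_index(drop=True)
        C, p, k, _ = dsep_test(dag, work, cov, binary_vertex=None)
        pvals.append(p)
        rejections += p < alpha
    return {"n_reps": n_reps, "rejections": rejections,
            "type1_rate": rejections / n_reps, "p_values": pvals}


def bpmm_gaussian_recovery(n_reps: int = 20, n_tips: int = 200, seed: int = 0,
                           h2_true: float = 0.7, slope_true: float = 0.17) -> dict:
    """Coverage of heritability and slope by the Gaussian BPMM."""
    rng = np.random.default_rng(seed)
    h2_cover = slope_cover = 0
    for rep in range(n_reps):
        tree = _random_tree(rng, n_tips)
        cov = tree.covariance()
        A = cov.matrix / np.max(np.diag(cov.matrix))
        n = n_tips
        x = rng.multivariate_normal(np.zeros(n), A, method="cholesky")
        a = rng.multivariate_normal(np.zeros(n), h2_true * A, method="cholesky")
        y = 1.0 + slope_true * x + a + rng.normal(0, np.sqrt(1 - h2_true), n)
        X = np.column_stack([np.ones(n), x])
        res = PhyloMixedModel(y, X, cov, exog_names=["(Intercept)", "x"]).fit(
            iterations=4_000, burn_in=500, thinning=5,
            seed=int(rng.integers(2**31)))
        h2 = res.heritability()
        h2_cover += h2["ci"][0] <= h2_true * 100 <= h2["ci"][1]
        s = res.summary().set_index("parameter").loc["x"]
        slope_cover += s["ci_lower"] <= slope_true <= s["ci_upper"]
    return {"n_reps": n_reps, "h2_covered": h2_cover, "slope_covered": slope_cover}


def bpmm_poisson_sign_recovery(n_reps: int = 20, n_tips: int = 150,
                               seed: int = 0, slope_true: float = 0.5) -> dict:
    """Sign recovery for the Poisson (caste-count) BPMM slope."""
    rng = np.random.default_rng(seed)
    hits = 0
    for rep in range(n_reps):
        tree = _random_tree(rng, n_tips)
        cov = tree.covariance()
        A = cov.matrix / np.max(np.diag(cov.matrix))
        n = n_tips
        x = rng.multivariate_normal(np.zeros(n), A, method="cholesky")
        a = rng.multivariate_normal(np.zeros(n), 0.3 * A, method="cholesky")
        y = rng.poisson(np.exp(0.3 + slope_true * x + a))
        X = np.column_stack([np.ones(n), x])
        res = PhyloMixedModel(y, X, cov, family="poisson_log",
                              exog_names=["(Intercept)", "x"]).fit(
            iterations=4_000, burn_in=500, thinning=5,
            seed=int(rng.integers(2**31)))
        s = res.summary().set_index("parameter").loc["x"]
        hits += np.sign(s["post_mode"]) == np.sign(slope_true)
    return {"n_reps": n_reps, "sign_recovered": hits}


def asr_contrast_recovery(n_reps: int = 20, n_tips: int = 150,
                          seed: int = 0) -> dict:
    """The ancestral-value contrast where origins sit on large-value lineages.

    Multiple castes are planted with a hard-zero gain rate below the median
    of a Brownian log colony size; success means the category-2 (pre-origin)
    ancestral mean exceeds the category-1 mean with pMCMC < 0.05.
    """
    hits = 0
    details = []
    for rep in range(n_reps):
        base = seed * 100_057 + rep * 13
        for attempt in range(20):
            s = base + attempt
            tree = simulate_yule(n_tips, seed=s * 7 + 1)
            h = tree.height()
            size = simulate_bm_on_nodes(tree, 1.44 / h, root_value=2.48,
                                        seed=s * 7 + 2)
            thr = float(np.median(size[:n_tips]))
            sim = simulate_dependent_binary(
                tree, size, threshold=thr, gain_rate_small=0.0,
                gain_rate_large=2.0 / h, loss_rate=0.2 / h, seed=s * 7 + 3)
            k1 = sum(sim.tip_states.values())
            # the planted regime keeps single castes dominant (as in the
            # empirical distribution) so origins, not losses, carry signal
            if 0.05 * n_tips <= k1 <= 0.45 * n_tips and sim.n_origins >= 3:
                break
        fit = HiddenRateModel(tree, sim.tip_states, n_obs=2,
                              n_rate_classes=1, structure="ard").fit(seed=s)
        assigned = fit.marginal_states().assigned_states()
        cats = classify_nodes(tree, assigned)
        vals = {lab: float(size[i]) for i, lab in enumerate(tree.tip_labels)}
        est = ancestral_value_regression(tree, cats, vals, iterations=3_000,
                                         burn_in=500, thinning=5, seed=s)
        ok = (est.pmcmc_1_vs_2 is not None and est.pmcmc_1_vs_2 < 0.05
              and est.categories[2]["mode"] > est.categories[1]["mode"])
        hits += ok
        details.append({"pmcmc": est.pmcmc_1_vs_2,
                        "mode_cat1": est.categories[1]["mode"],
                        "mode_cat2": est.categories[2]["mode"],
                        "n_origins_true": sim.n_origins})
    return {"n_reps": n_reps, "contrast_recovered": hits, "details": details}
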