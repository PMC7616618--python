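"""Correlated evolution of two binary traits on a phylogeny.

The dependent/independent contrast: two binary traits form a four-state
chain over (0,0), (0,1), (1,0), (1,1).  Under the independent model each
trait gains and loses regardless of the other (4 rates); under the
dependent model each single-trait transition rate is conditioned on the
current state of the other trait (8 rates).  Simultaneous changes of both
traits have rate zero.  Models are compared with Bayes factors
``2 * (log ml_dependent - log ml_independent)`` from stepping-stone
marginal likelihoods, and reversible-jump MCMC reports the posterior
probability that individual rates are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from . import markov
from .ss import MarginalLikelihood, SteppingStoneModel, stepping_stone_logml
from .treeio import Phylogeny, TreeSample, match_species_to_tips

__all__ = [
    "PAIR_STATES",
    "IND_RATE_NAMES",
    "DEP_RATE_NAMES",
    "RateModel",
    "build_generator",
    "DiscretePairCoevolution",
    "MLFit",
    "RJChain",
    "ExponentialHyperPrior",
    "GammaHyperPrior",
    "bayes_factor",
    "BayesFactor",
    "simulate_pair_ctmc",
    "pair_tip_partials",
]

# fixed state order used everywhere
PAIR_STATES = ((0, 0), (0, 1), (1, 0), (1, 1))

IND_RATE_NAMES = ("gain1", "loss1", "gain2", "loss2")
DEP_RATE_NAMES = (
    "gain1|2=0",  # (0,0) -> (1,0)
    "gain1|2=1",  # (0,1) -> (1,1)
    "loss1|2=0",  # (1,0) -> (0,0)
    "loss1|2=1",  # (1,1) -> (0,1)
    "gain2|1=0",  # (0,0) -> (0,1)
    "gain2|1=1",  # (1,0) -> (1,1)
    "loss2|1=0",  # (0,1) -> (0,0)
    "loss2|1=1",  # (1,1) -> (1,0)
)
# (from-state, to-state) per dependent rate, aligned with DEP_RATE_NAMES
_DEP_MOVES = ((0, 2), (1, 3), (2, 0), (3, 1), (0, 1), (2, 3), (1, 0), (3, 2))


def build_generator(kind: str, rates: Sequence[float]) -> np.ndarray:
    """4x4 generator for a pair of binary traits.

    ``kind='independent'`` expects 4 rates (trait-1 gain/loss, trait-2
    gain/loss); ``kind='dependent'`` expects 8 rates in the
    :data:`DEP_RATE_NAMES` order.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    if kind == "independent":
        if rates.shape != (4,):
            raise ValueError("independent model takes 4 rates")
        g1, l1, g2, l2 = rates
        dep = np.array([g1, g1, l1, l1, g2, g2, l2, l2])
    elif kind == "dependent":
        if rates.shape != (8,):
            raise ValueError("dependent model takes 8 rates")
        dep = rates
    else:
        raise ValueError(f"unknown kind {kind!r}")
    Q = np.zeros((4, 4))
    for r, (i, j) in zip(dep, _DEP_MOVES):
        Q[i, j] = r
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


@dataclass
class RateModel:
    """A fitted or specified pair-trait rate model."""

    kind: str
    rates: np.ndarray

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.names = IND_RATE_NAMES if self.kind == "independent" else DEP_RATE_NAMES
        if len(self.rates) != len(self.names):
            raise ValueError(
                f"{self.kind} model takes {len(self.names)} rates, got {len(self.rates)}"
            )

    @property
    def Q(self) -> np.ndarray:
        return build_generator(self.kind, self.rates)


def pair_tip_partials(
    tree: Phylogeny, tip_states: Mapping[str, tuple]
) -> np.ndarray:
    """Observation matrix over the four pair states.

    ``tip_states`` maps species to ``(trait1, trait2)`` with entries in
    {0, 1, None}; a missing trait leaves likelihood 1 over both compatible
    states.  Every tree tip must be present.
    """
    mapping, unmatched = match_species_to_tips(tip_states.keys(), tree.tip_labels)
    tipmap = {v: k for k, v in mapping.items()}
    missing = [t for t in tree.tip_labels if t not in tipmap]
    if missing:
        raise KeyError(f"tree tips without trait data: {missing}")
    partials = np.zeros((tree.n_tips, 4))
    for i, tip in enumerate(tree.tip_labels):
        s1, s2 = tip_states[tipmap[tip]]
        for j, (a, b) in enumerate(PAIR_STATES):
            ok1 = s1 is None or int(s1) == a
            ok2 = s2 is None or int(s2) == b
            if ok1 and ok2:
                partials[i, j] = 1.0
    return partials


# -- priors ----------------------------------------------------------------

@dataclass
class ExponentialHyperPrior:
    """Exponential rate prior whose mean is hyper-sampled uniform(lo, hi)."""

    lo: float = 0.0
    hi: float = 100.0

    def sample_hyper(self, rng) -> tuple:
        return (rng.uniform(max(self.lo, 1e-6), self.hi),)

    def hyper_in_bounds(self, hyper: tuple) -> bool:
        return self.lo < hyper[0] < self.hi

    def propose_hyper(self, hyper: tuple, rng) -> tuple:
        return (hyper[0] + rng.normal(0.0, 0.1 * (self.hi - self.lo)),)

    def log_rate_density(self, r: float, hyper: tuple) -> float:
        m = hyper[0]
        return -np.log(m) - r / m

    def sample_rate(self, rng, hyper: tuple) -> float:
        return float(rng.exponential(hyper[0]))


@dataclass
class GammaHyperPrior:
    """Gamma rate prior; mean and shape are each hyper-sampled uniformly."""

    mean_lo: float = 0.0
    mean_hi: float = 100.0
    shape_lo: float = 0.1
    shape_hi: float = 10.0

    def sample_hyper(self, rng) -> tuple:
        return (
            rng.uniform(max(self.mean_lo, 1e-6), self.mean_hi),
            rng.uniform(self.shape_lo, self.shape_hi),
        )

    def hyper_in_bounds(self, hyper: tuple) -> bool:
        m, k = hyper
        return self.mean_lo < m < self.mean_hi and self.shape_lo < k < self.shape_hi

    def propose_hyper(self, hyper: tuple, rng) -> tuple:
        m, k = hyper
        if rng.uniform() < 0.5:
            return (m + rng.normal(0.0, 0.1 * (self.mean_hi - self.mean_lo)), k)
        return (m, k + rng.normal(0.0, 0.1 * (self.shape_hi - self.shape_lo)))

    def log_rate_density(self, r: float, hyper: tuple) -> float:
        from scipy.stats import gamma as gamma_dist

        m, k = hyper
        return float(gamma_dist.logpdf(r, a=k, scale=m / k))

    def sample_rate(self, rng, hyper: tuple) -> float:
        m, k = hyper
        return float(rng.gamma(k, m / k))


# -- results containers ----------------------------------------------------

@dataclass
class MLFit:
    kind: str
    rates: np.ndarray
    loglik: float
    converged: bool
    at_boundary: bool
    n_starts: int
    rate_names: tuple = ()

    def summary(self) -> str:
        lines = [f"ML fit ({self.kind}): lnL = {self.loglik:.4f}"
                 + ("" if self.converged else "  [NOT CONVERGED]")
                 + ("  [boundary]" if self.at_boundary else "")]
        for name, r in zip(self.rate_names, self.rates):
            lines.append(f"  {name:>10s} = {r:.6g}")
        return "\n".join(lines)


@dataclass
class RJChain:
    """Posterior draws from the reversible-jump sampler."""

    kind: str
    rates: np.ndarray          # (n_kept, K), exact zeros where switched off
    hyper: np.ndarray          # (n_kept, n_hyper)
    loglik: np.ndarray
    rate_names: tuple
    iterations: int
    burn_in: int
    thinning: int
    seed: int
    tree_index: np.ndarray | None = None

    def zero_rate_proportion(self, rate: int | str) -> float:
        """Fraction of retained models in which a rate is exactly zero."""
        idx = self.rate_names.index(rate) if isinstance(rate, str) else int(rate)
        if not 0 <= idx < self.rates.shape[1]:
            raise IndexError(f"rate index {idx} out of range")
        if self.rates.shape[0] == 0:
            raise ValueError("empty chain")
        return float(np.mean(self.rates[:, idx] == 0.0))

    def ess(self) -> np.ndarray:
        import arviz as az

        return np.array([
            float(az.ess(az.convert_to_dataset(self.rates[None, :, i])["x"]))
            for i in range(self.rates.shape[1])
        ])

    def summary(self):
        import pandas as pd

        rows = []
        for i, name in enumerate(self.rate_names):
            r = self.rates[:, i]
            rows.append({
                "rate": name,
                "mean": float(r.mean()),
                "q2.5": float(np.quantile(r, 0.025)),
                "q97.5": float(np.quantile(r, 0.975)),
                "p_zero": float(np.mean(r == 0.0)),
            })
        return pd.DataFrame(rows)


@dataclass
class BayesFactor:
    bf: float
    label: str
    log_ml_dependent: float
    log_ml_independent: float


def bayes_factor(log_ml_dependent: float, log_ml_independent: float) -> BayesFactor:
    """``BF = 2 (log ml_dep - log ml_ind)`` with an evidence label.

    BF >= 2 is positive evidence for the dependent model, > 5 strong,
    > 10 very strong; BF <= 0 is no support.
    """
    if not (np.isfinite(log_ml_dependent) and np.isfinite(log_ml_independent)):
        raise ValueError("marginal likelihoods must be finite")
    bf = 2.0 * (log_ml_dependent - log_ml_independent)
    if bf > 10:
        label = "very strong"
    elif bf > 5:
        label = "strong"
    elif bf >= 2:
        label = "positive"
    elif bf > 0:
        label = "weak"
    else:
        label = "no support"
    return BayesFactor(bf, label, log_ml_dependent, log_ml_independent)


# -- the model class -------------------------------------------------------

class DiscretePairCoevolution:
    """Pair-trait coevolution model on a fixed tree (or a tree sample).

    Parameters
    ----------
    tree : Phylogeny
        Rooted time-calibrated tree.
    tip_states : mapping
        species -> (trait1, trait2) with entries in {0, 1, None}.
    root_prior : "uniform" or "stationary"
        Distribution over the four states at the root.
    """

    def __init__(self, tree: Phylogeny, tip_states: Mapping[str, tuple],
                 root_prior: str = "uniform"):
        self.tree = tree
        self.tip_states = dict(tip_states)
        if root_prior not in ("uniform", "stationary"):
            raise ValueError("root_prior must be 'uniform' or 'stationary'")
        self.root_prior_kind = root_prior
        self._engine = markov.PruningEngine(tree, pair_tip_partials(tree, tip_states))
        self._check_variation()

    def _check_variation(self):
        obs = [v for v in self.tip_states.values()]
        for t in (0, 1):
            vals = {s[t] for s in obs if s[t] is not None}
            if not vals:
                raise ValueError(f"trait {t + 1} entirely missing")
        self.constant_traits = [
            t for t in (0, 1)
            if len({s[t] for s in self.tip_states.values() if s[t] is not None}) < 2
        ]

    def _root_prior(self, Q: np.ndarray) -> np.ndarray:
        if self.root_prior_kind == "uniform":
            return np.full(4, 0.25)
        w, V = np.linalg.eig(Q.T)
        i = int(np.argmin(np.abs(w)))
        pi = np.abs(V[:, i].real)
        return pi / pi.sum()

    def loglik(self, model: RateModel) -> float:
        Q = model.Q
        return self._engine.loglik(Q, self._root_prior(Q))

    def loglik_rates(self, kind: str, rates: np.ndarray) -> float:
        Q = build_generator(kind, rates)
        return self._engine.loglik(Q, self._root_prior(Q))

    # -- maximum likelihood ------------------------------------------------
    def fit_ml(self, kind: str = "dependent", n_starts: int = 4, seed: int = 0) -> MLFit:
        """Multi-start L-BFGS maximisation of the pruning likelihood.

        The dependent fit always includes the expanded independent optimum
        as one start, so ``lnL_dependent >= lnL_independent`` holds for
        matched calls.
        """
        names = IND_RATE_NAMES if kind == "independent" else DEP_RATE_NAMES
        K = len(names)
        rng = np.random.default_rng(seed)
        height = max(self.tree.height(), 1e-9)

        def nll(logr):
            return -self.loglik_rates(kind, np.exp(logr))

        starts = [np.log(np.full(K, 1.0 / height))]
        for _ in range(n_starts - 1):
            starts.append(np.log(rng.uniform(0.05, 5.0, K) / height))
        if kind == "dependent":
            ind = self.fit_ml("independent", n_starts=max(2, n_starts - 1), seed=seed + 1)
            g1, l1, g2, l2 = np.maximum(ind.rates, 1e-8)
            starts.append(np.log(np.array([g1, g1, l1, l1, g2, g2, l2, l2])))
        best, ok = None, False
        bounds = [(-14.0, 9.0)] * K
        for x0 in starts:
            res = minimize(nll, np.clip(x0, -14, 9), method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best, ok = res, bool(res.success)
        rates = np.exp(best.x)
        at_boundary = bool(np.any(rates < 1e-5)) or bool(self.constant_traits)
        return MLFit(kind=kind, rates=rates, loglik=float(-best.fun),
                     converged=ok, at_boundary=at_boundary,
                     n_starts=len(starts), rate_names=names)

    # -- reversible jump ---------------------------------------------------
    def rjmcmc(
        self,
        kind: str = "dependent",
        prior: ExponentialHyperPrior | GammaHyperPrior | None = None,
        iterations: int = 11_000,
        burn_in: int = 1_000,
        thinning: int = 5,
        seed: int = 0,
        trees: TreeSample | None = None,
    ) -> RJChain:
        """RJ-MCMC over rate vectors with per-rate zero indicators.

        Moves: random-walk on log rates, zero/unzero toggles (prior-draw
        revival), and a random-walk on the hyper mean.  ``trees`` switches on
        tree resampling: each iteration draws one tree from the sample.
        """
        if prior is None:
            prior = ExponentialHyperPrior()
        if iterations <= burn_in:
            raise ValueError("iterations must exceed burn_in")
        names = IND_RATE_NAMES if kind == "independent" else DEP_RATE_NAMES
        K = len(names)
        rng = np.random.default_rng(seed)
        engines = [self._engine]
        if trees is not None:
            engines = [
                markov.PruningEngine(t, pair_tip_partials(t, self.tip_states))
                for t in trees
            ]
        cur_tree = 0

        def loglik_for(rates, tree_i):
            Q = build_generator(kind, rates)
            return engines[tree_i].loglik(Q, self._root_prior(Q))

        hyper = prior.sample_hyper(rng)
        rates = np.array([prior.sample_rate(rng, hyper) for _ in range(K)])
        active = np.ones(K, dtype=bool)
        ll = loglik_for(rates, cur_tree)
        kept_rates, kept_hyper, kept_ll, kept_tree = [], [], [], []
        for it in range(iterations):
            if trees is not None:
                # uniform tree prior over the posterior sample: MH move
                new_tree = int(rng.integers(len(engines)))
                new_ll = loglik_for(rates, new_tree)
                if np.log(rng.uniform()) < new_ll - ll:
                    cur_tree, ll = new_tree, new_ll
            # hyper update (prior-only acceptance over active rates)
            h_new = prior.propose_hyper(hyper, rng)
            if prior.hyper_in_bounds(h_new):
                lp_old = sum(prior.log_rate_density(r, hyper) for r in rates[active])
                lp_new = sum(prior.log_rate_density(r, h_new) for r in rates[active])
                if np.log(rng.uniform()) < lp_new - lp_old:
                    hyper = h_new
            # per-rate updates
            for i in rng.permutation(K):
                if rng.uniform() < 0.5:
                    # RJ toggle
                    new = rates.copy()
                    if active[i]:
                        new[i] = 0.0
                    else:
                        new[i] = prior.sample_rate(rng, hyper)
                    new_ll = loglik_for(new, cur_tree)
                    if np.log(rng.uniform()) < new_ll - ll:
                        rates, ll = new, new_ll
                        active[i] = not active[i]
                elif active[i]:
                    # multiplicative random walk, Jacobian r'/r
                    new = rates.copy()
                    new[i] = rates[i] * np.exp(rng.normal(0.0, 0.5))
                    lpr = (prior.log_rate_density(new[i], hyper)
                           - prior.log_rate_density(rates[i], hyper))
                    new_ll = loglik_for(new, cur_tree)
                    log_acc = new_ll - ll + lpr + np.log(new[i] / rates[i])
                    if np.log(rng.uniform()) < log_acc:
                        rates, ll = new, new_ll
            if it >= burn_in and (it - burn_in) % thinning == 0:
                kept_rates.append(rates.copy())
                kept_hyper.append(np.asarray(hyper, dtype=float))
                kept_ll.append(ll)
                kept_tree.append(cur_tree)
        return RJChain(
            kind=kind,
            rates=np.array(kept_rates),
            hyper=np.array(kept_hyper),
            loglik=np.array(kept_ll),
            rate_names=names,
            iterations=iterations,
            burn_in=burn_in,
            thinning=thinning,
            seed=seed,
            tree_index=np.array(kept_tree) if trees is not None else None,
        )

    # -- stepping stone ----------------------------------------------------
    def stepping_stone(
        self,
        kind: str = "dependent",
        prior: ExponentialHyperPrior | GammaHyperPrior | None = None,
        n_stones: int = 32,
        iters_per_stone: int = 150,
        burn_per_stone: int = 50,
        seed: int = 0,
    ) -> MarginalLikelihood:
        """Stepping-stone log marginal likelihood of one model kind.

        Runs over the fixed-dimension parameterisation (all rates free)
        under the hierarchical rate prior.
        """
        if prior is None:
            prior = ExponentialHyperPrior()
        model = _PairSSAdapter(self, kind, prior)
        return stepping_stone_logml(
            model, n_stones=n_stones, iters_per_stone=iters_per_stone,
            burn_per_stone=burn_per_stone, seed=seed,
        )


class _PairSSAdapter(SteppingStoneModel):
    """Stepping-stone adapter: state = (rates, hyper)."""

    def __init__(self, model: DiscretePairCoevolution, kind: str, prior):
        self.model = model
        self.kind = kind
        self.prior = prior
        self.K = 4 if kind == "independent" else 8

    def initial_state(self, rng):
        hyper = self.prior.sample_hyper(rng)
        rates = np.array([self.prior.sample_rate(rng, hyper) for _ in range(self.K)])
        return (rates, hyper)

    def log_prior(self, state):
        rates, hyper = state
        if not self.prior.hyper_in_bounds(hyper) or np.any(rates < 0):
            return -np.inf
        return float(sum(self.prior.log_rate_density(r, hyper) for r in rates))

    def log_lik(self, state):
        rates, _ = state
        return self.model.loglik_rates(self.kind, rates)

    @property
    def proposals(self):
        # a full scan per iteration: one random-walk move per rate, one
        # prior-redraw move and one hyper move (sequential Metropolis)
        def make_rw(i):
            def rw_rate(state, rng):
                rates, hyper = state
                new = rates.copy()
                new[i] = rates[i] * np.exp(rng.normal(0.0, 0.5))
                return (new, hyper), float(np.log(new[i] / rates[i]))

            return rw_rate

        def redraw_rate(state, rng):
            rates, hyper = state
            i = int(rng.integers(self.K))
            new = rates.copy()
            new[i] = self.prior.sample_rate(rng, hyper)
            log_h = (self.prior.log_rate_density(rates[i], hyper)
                     - self.prior.log_rate_density(new[i], hyper))
            return (new, hyper), float(log_h)

        def rw_hyper(state, rng):
            rates, hyper = state
            return (rates, self.prior.propose_hyper(hyper, rng)), 0.0

        rw_hyper.lik_invariant = True
        return [make_rw(i) for i in range(self.K)] + [redraw_rate, rw_hyper]


def simulate_pair_ctmc(
    tree: Phylogeny,
    model: RateModel,
    seed: int = 0,
    root_state: tuple | None = None,
    root_prior: np.ndarray | None = None,
):
    """Exact simulation of the pair chain down the tree.

    Returns ``(tip_states, simulation)`` where ``tip_states`` maps species to
    (trait1, trait2) tuples and ``simulation`` carries the full event log.
    """
    rng = np.random.default_rng(seed)
    rs = None if root_state is None else PAIR_STATES.index(tuple(root_state))
    sim = markov.simulate_ctmc(tree, model.Q, rng, root_state=rs, root_prior=root_prior)
    tips = {
        label: PAIR_STATES[sim.node_states[i]]
        for i, label in enumerate(tree.tip_labels)
    }
    return tips, sim
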