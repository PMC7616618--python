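"""Hidden rate models, ancestral states and the ancestral-value contrast.

A hidden rate model (HRM) expands each observed character state (single
versus multiple worker castes, or the 1-4 caste count) across latent rate
classes; transition rates between observed states are class-specific and
lineages switch class along the tree, capturing heterogeneity in the
tempo of caste evolution.  Candidate structures (equal-rates, symmetric,
all-rates-different x 1-3 rate classes) are ranked by AICc across a tree
sample.  Marginal ancestral probabilities classify every internal node
into four categories — (1) single caste, all descendants single;
(2) single caste, at least one descendant multiple; (3) multiple, all
descendants multiple; (4) multiple, at least one descendant single — and
an intercept-free phylogenetic mixed model with latent node values
estimates the continuous-trait value (colony size, mating frequency)
associated with each category, the 1-versus-2 contrast measuring the
trait value that preceded origins of multiple castes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import markov
from .bpmm import PhyloMixedModel, pmcmc_compare, posterior_mode_ci
from .treeio import Phylogeny, match_species_to_tips

__all__ = [
    "STRUCTURES",
    "hrm_parameter_count",
    "build_hrm_generator",
    "HiddenRateModel",
    "HRMResults",
    "aicc",
    "select_hrm",
    "NodeReconstruction",
    "classify_nodes",
    "count_origins",
    "transition_frequencies",
    "ancestral_value_regression",
    "AncestralEstimate",
]

STRUCTURES = ("equal_rates", "symmetric", "all_rates_different")
_ALIASES = {"er": "equal_rates", "sym": "symmetric", "ard": "all_rates_different"}


def _canon_structure(structure: str) -> str:
    s = _ALIASES.get(structure.lower(), structure)
    if s not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    return s


def _obs_rate_index(n_obs: int, structure: str) -> list[tuple[int, int, int]]:
    """(i, j, param-slot) for observed-state transitions within one class."""
    out = []
    slot = 0
    if structure == "equal_rates":
        for i in range(n_obs):
            for j in range(n_obs):
                if i != j:
                    out.append((i, j, 0))
        return out
    if structure == "symmetric":
        pair_slot = {}
        for i in range(n_obs):
            for j in range(n_obs):
                if i == j:
                    continue
                key = (min(i, j), max(i, j))
                if key not in pair_slot:
                    pair_slot[key] = slot
                    slot += 1
                out.append((i, j, pair_slot[key]))
        return out
    for i in range(n_obs):
        for j in range(n_obs):
            if i != j:
                out.append((i, j, slot))
                slot += 1
    return out


def hrm_parameter_count(n_obs: int, n_classes: int, structure: str) -> int:
    structure = _canon_structure(structure)
    per_class = {
        "equal_rates": 1,
        "symmetric": n_obs * (n_obs - 1) // 2,
        "all_rates_different": n_obs * (n_obs - 1),
    }[structure]
    return per_class * n_classes + (1 if n_classes > 1 else 0)


def build_hrm_generator(
    n_obs: int, n_classes: int, structure: str, params: np.ndarray
) -> np.ndarray:
    """Expanded generator over (observed state, rate class) pairs.

    State index = class * n_obs + observed.  The parameter vector holds the
    per-class observed-transition rates (structure-dependent count per
    class) followed by a single class-switch rate; simultaneous changes of
    observed state and class have rate zero.
    """
    structure = _canon_structure(structure)
    params = np.asarray(params, float)
    if len(params) != hrm_parameter_count(n_obs, n_classes, structure):
        raise ValueError("parameter vector has the wrong length")
    moves = _obs_rate_index(n_obs, structure)
    per_class = max(s for _, _, s in moves) + 1
    m = n_obs * n_classes
    Q = np.zeros((m, m))
    for c in range(n_classes):
        block = params[c * per_class:(c + 1) * per_class]
        for i, j, slot in moves:
            Q[c * n_obs + i, c * n_obs + j] = block[slot]
    if n_classes > 1:
        switch = params[-1]
        for c1 in range(n_classes):
            for c2 in range(n_classes):
                if c1 != c2:
                    for s in range(n_obs):
                        Q[c1 * n_obs + s, c2 * n_obs + s] = switch
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def aicc(loglik: float, k: int, n: int) -> float:
    """Corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return float(-2.0 * loglik + 2 * k + 2.0 * k * (k + 1) / (n - k - 1))


@dataclass
class HRMResults:
    """A fitted hidden rate model."""

    n_obs: int
    n_rate_classes: int
    structure: str
    rates: np.ndarray
    loglik: float
    k: int
    aicc: float
    converged: bool
    model: "HiddenRateModel"

    @property
    def Q(self) -> np.ndarray:
        return build_hrm_generator(self.n_obs, self.n_rate_classes,
                                   self.structure, self.rates)

    def marginal_states(self) -> "NodeReconstruction":
        """Marginal observed-state probabilities with classes summed out."""
        m = self.model
        probs = markov.marginal_node_probabilities(
            m.tree, self.Q, m.tip_partials, m.root_prior
        )
        n_obs = self.n_obs
        collapsed = probs.reshape(probs.shape[0], self.n_rate_classes, n_obs).sum(axis=1)
        return NodeReconstruction(tree=m.tree, probabilities=collapsed,
                                  tip_states=m.tip_states)

    def summary(self) -> str:
        return (
            f"HRM {self.structure} x {self.n_rate_classes} classes, "
            f"{self.n_obs} observed states: lnL = {self.loglik:.4f}, "
            f"k = {self.k}, AICc = {self.aicc:.4f}"
            + ("" if self.converged else "  [NOT CONVERGED]")
        )


class HiddenRateModel:
    """ML hidden-rate model for one discrete character on one tree.

    ``tip_states`` maps species to observed states ``0..n_obs-1`` (None
    for missing); the latent rate class is never observed, so each tip is
    ambiguous across the classes compatible with its observed state.
    """

    def __init__(
        self,
        tree: Phylogeny,
        tip_states: Mapping[str, int | None],
        n_obs: int = 2,
        n_rate_classes: int = 1,
        structure: str = "equal_rates",
    ):
        if n_rate_classes not in (1, 2, 3):
            raise ValueError("supported rate-class counts are 1-3")
        self.tree = tree
        self.n_obs = n_obs
        self.n_rate_classes = n_rate_classes
        self.structure = _canon_structure(structure)
        self.tip_states = dict(tip_states)
        mapping, _ = match_species_to_tips(tip_states.keys(), tree.tip_labels)
        rev = {v: k for k, v in mapping.items()}
        missing = [t for t in tree.tip_labels if t not in rev]
        if missing:
            raise KeyError(f"tree tips without states: {missing}")
        m = n_obs * n_rate_classes
        partials = np.zeros((tree.n_tips, m))
        for i, tip in enumerate(tree.tip_labels):
            s = tip_states[rev[tip]]
            for c in range(n_rate_classes):
                if s is None:
                    partials[i, c * n_obs:(c + 1) * n_obs] = 1.0
                else:
                    partials[i, c * n_obs + int(s)] = 1.0
        self.tip_partials = partials
        self.root_prior = np.full(m, 1.0 / m)
        self._engine = markov.PruningEngine(tree, partials)
        self.k = hrm_parameter_count(n_obs, n_rate_classes, self.structure)

    def loglik(self, params: np.ndarray) -> float:
        Q = build_hrm_generator(self.n_obs, self.n_rate_classes, self.structure, params)
        return self._engine.loglik(Q, self.root_prior)

    def fit(self, n_starts: int = 3, seed: int = 0) -> HRMResults:
        rng = np.random.default_rng(seed)
        height = max(self.tree.height(), 1e-9)

        def nll(logp):
            return -self.loglik(np.exp(logp))

        starts = [np.log(np.full(self.k, 1.0 / height))]
        for _ in range(n_starts - 1):
            starts.append(np.log(rng.uniform(0.05, 5.0, self.k) / height))
        best, ok = None, False
        for x0 in starts:
            res = minimize(nll, np.clip(x0, -14, 9), method="L-BFGS-B",
                           bounds=[(-14.0, 9.0)] * self.k)
            if best is None or res.fun < best.fun:
                best, ok = res, bool(res.success)
        ll = float(-best.fun)
        return HRMResults(
            n_obs=self.n_obs, n_rate_classes=self.n_rate_classes,
            structure=self.structure, rates=np.exp(best.x), loglik=ll,
            k=self.k, aicc=aicc(ll, self.k, self.tree.n_tips),
            converged=ok, model=self,
        )


def select_hrm(
    trees: Sequence[Phylogeny],
    tip_states: Mapping[str, int | None],
    n_obs: int = 2,
    candidates: Sequence[tuple[int, str]] | None = None,
    n_starts: int = 3,
    seed: int = 0,
) -> dict:
    """Fit a candidate set per tree; the winner has the lowest AICc on the
    largest fraction of trees (ties break toward fewer parameters)."""
    if candidates is None:
        candidates = [(c, s) for c in (1, 2, 3) for s in STRUCTURES]
    candidates = [(c, _canon_structure(s)) for c, s in candidates]
    rows = []
    wins = {cand: 0 for cand in candidates}
    for ti, tree in enumerate(trees):
        fits = {}
        for c, s in candidates:
            fit = HiddenRateModel(tree, tip_states, n_obs=n_obs,
                                  n_rate_classes=c, structure=s).fit(
                                      n_starts=n_starts, seed=seed + ti)
            fits[(c, s)] = fit
            rows.append({"tree": ti, "n_rate_classes": c, "structure": s,
                         "lnL": fit.loglik, "k": fit.k, "AICc": fit.aicc})
        best = min(fits, key=lambda cand: (round(fits[cand].aicc, 9), fits[cand].k))
        wins[best] += 1
    table = pd.DataFrame(rows)
    n_trees = len(list(trees))
    winner = max(wins, key=lambda cand: (wins[cand], -hrm_parameter_count(
        n_obs, cand[0], cand[1])))
    return {
        "winner": {"n_rate_classes": winner[0], "structure": winner[1]},
        "win_fraction": wins[winner] / n_trees,
        "wins": {f"{c}x{s}": w for (c, s), w in wins.items()},
        "table": table,
    }


@dataclass
class NodeReconstruction:
    """Marginal state probabilities and assignments for every node."""

    tree: Phylogeny
    probabilities: np.ndarray  # (n_nodes, n_obs), rows sum to 1
    tip_states: dict

    def assigned_states(self, tie_state: int = 0) -> np.ndarray:
        """Argmax states; exact 0.5 ties go to ``tie_state`` with a warning."""
        p = self.probabilities
        assigned = p.argmax(axis=1)
        ties = np.abs(p.max(axis=1) - 0.5) < 1e-12 if p.shape[1] == 2 else np.zeros(
            p.shape[0], dtype=bool)
        if ties.any():
            warnings.warn(f"{int(ties.sum())} node(s) with tied marginals "
                          f"assigned to state {tie_state}")
            assigned[ties] = tie_state
        return assigned


def classify_nodes(
    tree: Phylogeny, assigned: np.ndarray
) -> np.ndarray:
    """Four-way classification of internal nodes from binary assignments.

    ``assigned`` holds the 0/1 (single/multiple) state of every node, tips
    included.  Category: 1 = single & all descendants single, 2 = single &
    some descendant multiple, 3 = multiple & all multiple, 4 = multiple &
    some descendant single.  Tip entries of the returned array use the
    degenerate rule (no descendants): single -> 1, multiple -> 3.
    """
    ix = tree.index
    if set(np.unique(assigned)) - {0, 1}:
        raise ValueError("classification is defined for binary states")
    any_single = np.zeros(ix.n_nodes, dtype=bool)
    any_multiple = np.zeros(ix.n_nodes, dtype=bool)
    cat = np.zeros(ix.n_nodes, dtype=np.int64)
    for v in range(ix.n_tips):
        any_single[v] = assigned[v] == 0
        any_multiple[v] = assigned[v] == 1
        cat[v] = 1 if assigned[v] == 0 else 3
    for v in ix.postorder:
        a_s = a_m = False
        for c in ix.children(v):
            a_s |= any_single[c]
            a_m |= any_multiple[c]
        if assigned[v] == 0:
            cat[v] = 2 if a_m else 1
        else:
            cat[v] = 4 if a_s else 3
        any_single[v] = a_s or assigned[v] == 0
        any_multiple[v] = a_m or assigned[v] == 1
    return cat


def count_origins(tree: Phylogeny, assigned: np.ndarray) -> int:
    """Edges whose parent is single (0) and child multiple (1)."""
    ix = tree.index
    n = 0
    for v in range(ix.n_nodes):
        p = ix.parent[v]
        if p >= 0 and assigned[p] == 0 and assigned[v] == 1:
            n += 1
    return n


def transition_frequencies(tree: Phylogeny, assigned: np.ndarray, n_obs: int) -> np.ndarray:
    """Counts of parent-to-child assigned-state changes (n_obs x n_obs)."""
    ix = tree.index
    freq = np.zeros((n_obs, n_obs), dtype=np.int64)
    for v in range(ix.n_nodes):
        p = ix.parent[v]
        if p >= 0:
            freq[assigned[p], assigned[v]] += 1
    return freq


@dataclass
class AncestralEstimate:
    """Per-category ancestral trait estimates and the 1-vs-2 contrast."""

    categories: dict                  # cat -> {mode, ci, n_members, flagged}
    pmcmc_1_vs_2: float | None
    response_scale: str
    results: object = field(repr=False, default=None)

    def back_transformed(self) -> dict:
        """Estimates on the measurement scale (inverse log10)."""
        if self.response_scale != "log10":
            raise ValueError("response was not modelled on a log10 scale")
        out = {}
        for cat, d in self.categories.items():
            out[cat] = {
                "mode": 10.0 ** d["mode"],
                "ci": (10.0 ** d["ci"][0], 10.0 ** d["ci"][1]),
                "n_members": d["n_members"],
            }
        return out


def ancestral_value_regression(
    tree: Phylogeny,
    node_categories: np.ndarray,
    tip_values: Mapping[str, float],
    iterations: int = 4_000,
    burn_in: int = 500,
    thinning: int = 5,
    seed: int = 0,
    response_scale: str = "log10",
    prior=None,
) -> AncestralEstimate:
    """Ancestral-value contrast between node classification categories.

    Tip values are observed; internal-node values are latent, tied to the
    tips through the node-inclusive phylogenetic covariance in a BPMM.
    Each posterior draw yields every node's ancestral value (intercept plus
    node-level phylogenetic effect); averaging those draws within a
    classification category gives one posterior sample of that category's
    mean, so each category has its own estimated level (no shared global
    intercept constrains them) and the category-1 versus category-2 pMCMC
    measures whether the trait differed in ancestors that went on to evolve
    multiple castes.  A category whose draws would rest on latent values
    only is fully identified here because node values are predictions from
    the observed tips, not free parameters.
    """
    ix = tree.index
    cov = tree.covariance(include_internal=True)
    n_total = ix.n_nodes
    y = np.full(n_total, np.nan)
    mapping, _ = match_species_to_tips(tip_values.keys(), tree.tip_labels)
    tip_pos = {lab: i for i, lab in enumerate(tree.tip_labels)}
    for sp, lab in mapping.items():
        v = tip_values[sp]
        if v is not None and np.isfinite(v):
            y[tip_pos[lab]] = float(v)
    if np.isnan(y[: ix.n_tips]).all():
        raise ValueError("no tip has an observed trait value")
    cats = np.asarray(node_categories, dtype=int)
    if cats.shape[0] != n_total:
        raise ValueError("need one category per node (tips included)")
    X = np.ones((n_total, 1))
    model = PhyloMixedModel(y, X, cov, family="gaussian",
                            exog_names=["(Intercept)"], prior=prior,
                            taxa=cov.taxa)
    res = model.fit(iterations=iterations, burn_in=burn_in, thinning=thinning,
                    seed=seed)
    # latent draws cover the NaN rows in row order; map back to node indices
    latent = np.concatenate([c["latent"] for c in res.chains])  # (draws, n_missing)
    miss_rows = np.where(np.isnan(y))[0]
    internal = np.array([v for v in miss_rows if v >= ix.n_tips])
    col = {v: j for j, v in enumerate(miss_rows)}
    levels = [1, 2, 3, 4]
    categories = {}
    cat_draws = {}
    for lv in levels:
        members = internal[cats[internal] == lv]
        n_members = int(len(members))
        if n_members == 0:
            categories[lv] = {"mode": np.nan, "ci": (np.nan, np.nan),
                              "n_members": 0, "flagged": True}
            continue
        draws = latent[:, [col[v] for v in members]].mean(axis=1)
        cat_draws[lv] = draws
        mode, ci = posterior_mode_ci(draws)
        categories[lv] = {"mode": mode, "ci": ci, "n_members": n_members,
                          "flagged": n_members < 2}
    p12 = None
    if 1 in cat_draws and 2 in cat_draws:
        p12 = pmcmc_compare(cat_draws[1], cat_draws[2])
    est = AncestralEstimate(categories=categories, pmcmc_1_vs_2=p12,
                            response_scale=response_scale, results=res)
    est.category_draws = cat_draws
    return est
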