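"""Phylogenetic path analysis.

Candidate causal DAGs over {worker-caste complexity, colony size, queen
mating frequency, queen number} are tested by the d-separation method:
each DAG implies conditional independencies (one per non-adjacent vertex
pair, conditioned on the union of both vertices' parents), each claim is
tested with a phylogenetic regression (PGLS with Pagel's lambda for
continuous responses, a phylogenetic logistic regression for the binary
caste variable), the claim p-values combine into Fisher's C, and models
are ranked by CICc.  Supported models (delta CICc < 2) are averaged with
CICc weights, absent paths contributing coefficient and variance zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, norm, t as t_dist

from .treeio import Phylogeny, PhyloCovariance

__all__ = [
    "CausalDAG",
    "IndependenceClaim",
    "candidate_models",
    "basis_set",
    "PGLS",
    "PGLSResults",
    "PhyloLogistic",
    "dsep_test",
    "cicc",
    "rank_models",
    "average_paths",
    "run_candidate_set",
    "PathFitResult",
]


class CausalDAG:
    """A named acyclic causal hypothesis over trait vertices."""

    def __init__(self, name: str, edges: Sequence[tuple[str, str]],
                 vertices: Sequence[str] | None = None):
        g = nx.DiGraph()
        if vertices:
            g.add_nodes_from(vertices)
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError(f"{name}: causal model must be acyclic")
        self.name = name
        self.graph = g

    @classmethod
    def from_edge_list(cls, name: str, text: str) -> "CausalDAG":
        """Parse an ``A -> B`` per-line edge list."""
        edges = []
        for line in text.strip().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            lhs, rhs = [s.strip() for s in line.split("->")]
            edges.append((lhs, rhs))
        return cls(name, edges)

    @property
    def vertices(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def parents(self, v: str) -> set[str]:
        return set(self.graph.predecessors(v))


@dataclass(frozen=True)
class IndependenceClaim:
    """X independent of Y given the union of both parent sets."""

    x: str
    y: str
    conditioning: tuple[str, ...]
    response: str  # topologically later vertex (ties alphabetical)

    @property
    def predictor(self) -> str:
        return self.y if self.response == self.x else self.x


def candidate_models(complexity: str = "castes") -> dict[str, CausalDAG]:
    """The four built-in causal hypotheses.

    Every model contains queen_number -> mating_frequency and
    colony_size -> mating_frequency.  They differ in what drives the
    complexity vertex (number of worker castes, or worker-size variation):

    - model_1: colony_size -> complexity (mating frequency does not act)
    - model_2: complexity -> colony_size
    - model_3: colony_size -> complexity and mating_frequency -> complexity
    - model_4: mating_frequency -> complexity (colony size does not act)
    """
    base = [("queen_number", "mating_frequency"), ("colony_size", "mating_frequency")]
    extras = {
        "model_1": [("colony_size", complexity)],
        "model_2": [(complexity, "colony_size")],
        "model_3": [("colony_size", complexity), ("mating_frequency", complexity)],
        "model_4": [("mating_frequency", complexity)],
    }
    verts = [complexity, "colony_size", "mating_frequency", "queen_number"]
    return {name: CausalDAG(name, base + extra, vertices=verts)
            for name, extra in extras.items()}


def basis_set(dag: CausalDAG) -> list[IndependenceClaim]:
    """The d-separation basis set of a DAG.

    One claim per non-adjacent vertex pair, conditioned on the union of the
    two parent sets; the regression response is the topologically later
    vertex, ties broken alphabetically.  Deterministic ordering.
    """
    order = list(nx.lexicographical_topological_sort(dag.graph))
    rank = {v: i for i, v in enumerate(order)}
    claims = []
    for x, y in itertools.combinations(sorted(dag.graph.nodes), 2):
        if dag.graph.has_edge(x, y) or dag.graph.has_edge(y, x):
            continue
        cond = tuple(sorted((dag.parents(x) | dag.parents(y)) - {x, y}))
        response = x if rank[x] > rank[y] else y
        claims.append(IndependenceClaim(x=x, y=y, conditioning=cond, response=response))
    return claims


# -- phylogenetic regressions ---------------------------------------------

@dataclass
class PGLSResults:
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    lam: float
    loglik: float
    nobs: int
    df_resid: int
    exog_names: list[str]

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        q = t_dist.ppf(1 - alpha / 2, self.df_resid)
        return np.column_stack([self.params - q * self.bse, self.params + q * self.bse])

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "coef": self.params, "se": self.bse, "p": self.pvalues,
            "ci_lower": ci[:, 0], "ci_upper": ci[:, 1],
        }, index=self.exog_names)


class PGLS:
    """Phylogenetic generalized least squares with Pagel's lambda.

    ``lam=None`` profiles lambda in [0, 1] by maximum likelihood;
    ``lam=0`` is exactly ordinary least squares.
    """

    def __init__(self, endog, exog, covariance: PhyloCovariance | np.ndarray,
                 exog_names: Sequence[str] | None = None):
        self.y = np.asarray(endog, float)
        X = np.asarray(exog, float)
        self.X = X if X.ndim == 2 else X[:, None]
        C = covariance.matrix if isinstance(covariance, PhyloCovariance) else np.asarray(covariance)
        self.C = C / np.max(np.diag(C))
        n, p = self.X.shape
        if np.linalg.matrix_rank(self.X) < p:
            raise np.linalg.LinAlgError("singular design matrix")
        self.exog_names = list(exog_names) if exog_names else [f"x{i}" for i in range(p)]

    def _gls(self, lam: float):
        n, p = self.X.shape
        V = lam * self.C + np.diag(np.diag(self.C) * (1 - lam))
        cf = cho_factor(V + 1e-10 * np.eye(n))
        Vy = cho_solve(cf, self.y)
        VX = cho_solve(cf, self.X)
        XtVX = self.X.T @ VX
        beta = np.linalg.solve(XtVX, self.X.T @ Vy)
        resid = self.y - self.X @ beta
        Vr = cho_solve(cf, resid)
        rss = float(resid @ Vr)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
        return beta, XtVX, rss, ll

    def fit(self, lam: float | None = None) -> PGLSResults:
        n, p = self.X.shape
        if lam is None:
            res = minimize_scalar(lambda l: -self._gls(l)[3], bounds=(0.0, 1.0),
                                  method="bounded", options={"xatol": 1e-4})
            lam = float(res.x)
            # the bounded optimiser never quite reaches the edges
            for edge in (0.0, 1.0):
                if -self._gls(edge)[3] <= -self._gls(lam)[3]:
                    lam = edge
        beta, XtVX, rss, ll = self._gls(lam)
        sigma2 = rss / (n - p)
        bse = np.sqrt(np.diag(np.linalg.inv(XtVX)) * sigma2)
        tvals = beta / bse
        pvals = 2 * t_dist.sf(np.abs(tvals), n - p)
        return PGLSResults(params=beta, bse=bse, pvalues=pvals, lam=lam,
                           loglik=ll, nobs=n, df_resid=n - p,
                           exog_names=self.exog_names)


@dataclass
class PhyloLogisticResults:
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    sigma2: float
    nobs: int
    exog_names: list[str]
    separation: bool = False

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse, "p": self.pvalues},
                            index=self.exog_names)


class PhyloLogistic:
    """Phylogenetically corrected logistic regression (PQL).

    A logistic GLMM with random effect ``a ~ N(0, sigma2 * C)`` fitted by
    penalised quasi-likelihood; ``sigma2`` is chosen on a coarse grid by an
    approximate REML criterion.  At ``sigma2 = 0`` the fit is the ordinary
    logistic regression (delegated to statsmodels).  Complete separation is
    flagged and handled with a small ridge penalty.
    """

    SIGMA_GRID = (0.0, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2)

    def __init__(self, endog, exog, covariance: PhyloCovariance | np.ndarray,
                 exog_names: Sequence[str] | None = None):
        self.y = np.asarray(endog, float)
        if set(np.unique(self.y)) - {0.0, 1.0}:
            raise ValueError("response must be binary 0/1")
        if len(np.unique(self.y)) < 2:
            raise ValueError("binary response is constant")
        X = np.asarray(exog, float)
        self.X = X if X.ndim == 2 else X[:, None]
        C = covariance.matrix if isinstance(covariance, PhyloCovariance) else np.asarray(covariance)
        self.C = C / np.max(np.diag(C))
        self.exog_names = list(exog_names) if exog_names else [f"x{i}" for i in range(self.X.shape[1])]

    def _pql(self, sigma2: float, ridge: float = 0.0):
        n, p = self.X.shape
        b = np.zeros(p)
        a = np.zeros(n)
        crit_prev = None
        for _ in range(50):
            eta = self.X @ b + a
            mu = 1.0 / (1.0 + np.exp(-eta))
            W = np.clip(mu * (1 - mu), 1e-6, None)
            z = eta + (self.y - mu) / W
            V = sigma2 * self.C + np.diag(1.0 / W)
            cf = cho_factor(V)
            VX = cho_solve(cf, self.X)
            XtVX = self.X.T @ VX + ridge * np.eye(p)
            bse_mat = np.linalg.inv(XtVX)
            b_new = bse_mat @ (self.X.T @ cho_solve(cf, z))
            r = z - self.X @ b_new
            a = sigma2 * (self.C @ cho_solve(cf, r))
            if np.linalg.norm(b_new - b) < 1e-8 * (1 + np.linalg.norm(b)):
                b = b_new
                break
            b = b_new
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        Vr = cho_solve(cf, z - self.X @ b)
        crit = -0.5 * (logdet + float((z - self.X @ b) @ Vr)
                       + float(np.linalg.slogdet(XtVX)[1]))
        return b, bse_mat, crit

    def fit(self) -> PhyloLogisticResults:
        import statsmodels.api as sm

        n, p = self.X.shape
        separation = False
        try:
            with np.errstate(all="ignore"):
                glm = sm.GLM(self.y, self.X, family=sm.families.Binomial()).fit(maxiter=100)
            if np.any(np.abs(glm.params) > 15) or np.any(~np.isfinite(glm.bse)):
                separation = True
        except Exception:
            separation = True
        ridge = 0.5 if separation else 0.0
        best = None
        for s2 in self.SIGMA_GRID:
            b, cov_b, crit = self._pql(s2, ridge=ridge)
            if best is None or crit > best[3]:
                best = (s2, b, cov_b, crit)
        s2, b, cov_b, _ = best
        if s2 == 0.0 and not separation:
            params, bse = glm.params, glm.bse
        else:
            params, bse = b, np.sqrt(np.diag(cov_b))
        z = params / bse
        pvals = 2 * norm.sf(np.abs(z))
        return PhyloLogisticResults(params=np.asarray(params), bse=np.asarray(bse),
                                    pvalues=pvals, sigma2=s2, nobs=n,
                                    exog_names=self.exog_names,
                                    separation=separation)


# -- d-separation, CICc, averaging ----------------------------------------

def _claim_pvalue(claim: IndependenceClaim, data: pd.DataFrame,
                  cov: PhyloCovariance, binary_vertex: str | None):
    resp = claim.response
    pred = claim.predictor
    cols = [pred] + list(claim.conditioning)
    X = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(float) for c in cols])
    names = ["(Intercept)"] + cols
    y = data[resp].to_numpy(float)
    if binary_vertex is not None and resp == binary_vertex:
        fit = PhyloLogistic(y, X, cov, exog_names=names).fit()
    else:
        fit = PGLS(y, X, cov, exog_names=names).fit()
    return float(fit.pvalues[1]), fit


def dsep_test(dag: CausalDAG, data: pd.DataFrame, cov: PhyloCovariance,
              binary_vertex: str | None = None):
    """Fisher's C over the DAG's basis set.

    ``C = -2 sum ln p_i`` is chi-square with ``2k`` degrees of freedom when
    the causal model is correct; p < 0.05 rejects the model.  A complete
    DAG has an empty basis set and is trivially accepted (C = 0, p = 1).
    """
    claims = basis_set(dag)
    pvals, fits = [], []
    for cl in claims:
        try:
            p, fit = _claim_pvalue(cl, data, cov, binary_vertex)
        except Exception as exc:
            raise RuntimeError(f"claim {cl.x} _||_ {cl.y} | {cl.conditioning}: {exc}") from exc
        pvals.append(max(p, 1e-300))
        fits.append(fit)
    k = len(claims)
    C = float(-2.0 * np.sum(np.log(pvals))) if k else 0.0
    p_C = float(chi2.sf(C, 2 * k)) if k else 1.0
    return C, p_C, k, list(zip(claims, pvals))


def cicc(C: float, q: int, n: int) -> float:
    """The C-statistic information criterion, small-sample corrected.

    ``CICc = C + 2 q n / (n - 1 - q)`` with ``q`` the parameter count.
    """
    if n <= q + 1:
        raise ValueError(f"need n > q + 1 (n={n}, q={q})")
    return float(C + 2.0 * q * n / (n - 1 - q))


@dataclass
class PathFitResult:
    """Per-DAG d-sep fit."""

    name: str
    C: float
    p_C: float
    k: int
    q: int
    n: int
    CICc: float
    delta_cicc: float = np.nan
    omega: float = np.nan
    coefficients: pd.DataFrame | None = None  # per-edge standardized beta, se
    claims: list = field(default_factory=list)


def rank_models(fits: Sequence[PathFitResult]) -> pd.DataFrame:
    """Delta CICc and CICc weights; the supported set is delta < 2."""
    if len(fits) < 2:
        raise ValueError("ranking needs at least two candidate models")
    cs = np.array([f.CICc for f in fits])
    delta = cs - cs.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    for f, d, o in zip(fits, delta, w):
        f.delta_cicc = float(d)
        f.omega = float(o)
    rows = [{
        "model": f.name, "C": f.C, "p_C": f.p_C, "k_claims": f.k, "q": f.q,
        "CICc": f.CICc, "delta_CICc": f.delta_cicc, "omega": f.omega,
        "supported": f.delta_cicc < 2.0, "rejected_by_dsep": f.p_C < 0.05,
    } for f in fits]
    return pd.DataFrame(rows).sort_values("CICc").reset_index(drop=True)


def average_paths(fits: Sequence[PathFitResult]) -> pd.DataFrame:
    """CICc-weight-averaged standardized path coefficients.

    Weights renormalise over the supported set; a path absent from a model
    contributes coefficient 0 with variance 0 (full averaging).
    """
    supported = [f for f in fits if f.delta_cicc < 2.0]
    if not supported:
        raise ValueError("no supported models (delta CICc < 2)")
    w = np.array([f.omega for f in supported])
    w = w / w.sum()
    edges = sorted({e for f in supported for e in f.coefficients.index})
    rows = []
    for e in edges:
        beta = np.zeros(len(supported))
        var = np.zeros(len(supported))
        for i, f in enumerate(supported):
            if e in f.coefficients.index:
                beta[i] = f.coefficients.loc[e, "beta"]
                var[i] = f.coefficients.loc[e, "se"] ** 2
        avg_beta = float(w @ beta)
        avg_var = float(w @ var)
        se = np.sqrt(avg_var)
        rows.append({
            "edge": e, "beta": avg_beta, "se": se,
            "ci_lower": avg_beta - 1.96 * se, "ci_upper": avg_beta + 1.96 * se,
        })
    if not rows:
        return pd.DataFrame(
            columns=["beta", "se", "ci_lower", "ci_upper"],
            index=pd.Index([], name="edge"))
    return pd.DataFrame(rows).set_index("edge")


def _path_coefficients(dag: CausalDAG, data: pd.DataFrame, cov: PhyloCovariance,
                       binary_vertex: str | None) -> pd.DataFrame:
    rows = []
    for v in dag.vertices:
        parents = sorted(dag.parents(v))
        if not parents:
            continue
        X = np.column_stack([np.ones(len(data))] + [data[p].to_numpy(float) for p in parents])
        names = ["(Intercept)"] + parents
        y = data[v].to_numpy(float)
        if binary_vertex is not None and v == binary_vertex:
            fit = PhyloLogistic(y, X, cov, exog_names=names).fit()
        else:
            fit = PGLS(y, X, cov, exog_names=names).fit()
        for j, p in enumerate(parents, start=1):
            rows.append({"edge": f"{p} -> {v}", "beta": float(fit.params[j]),
                         "se": float(fit.bse[j])})
    return pd.DataFrame(rows).set_index("edge") if rows else pd.DataFrame(
        columns=["beta", "se"])


def run_candidate_set(
    data: pd.DataFrame,
    tree: Phylogeny,
    response_mode: str = "castes_binary",
    species_column: str = "species",
) -> dict:
    """Evaluate the four causal hypotheses, rank them and average paths.

    ``response_mode``:

    - ``castes_binary``: the complexity vertex is the single/multiple caste
      indicator, tested with phylogenetic logistic regression.
    - ``worker_cv``: square-root worker-size CV, all species.
    - ``worker_cv_monomorphic_only``: same, restricted to species with a
      single worker caste.

    Continuous variables are z-scored so path coefficients are
    standardized.  Returns a dict with per-model fits, the ranking table
    and the averaged model.
    """
    if response_mode == "castes_binary":
        complexity_col, binary = "castes_multiple", "castes_multiple"
        work = data.copy()
        if "castes_multiple" not in work.columns:
            if "castes_binary" in work.columns:
                work["castes_multiple"] = (work["castes_binary"] == "multiple").astype(float)
            elif "castes" in work.columns:
                work["castes_multiple"] = (work["castes"].astype(float) > 1).astype(float)
            else:
                raise KeyError("no caste column available")
    elif response_mode in ("worker_cv", "worker_cv_monomorphic_only"):
        complexity_col, binary = "sqrt_worker_cv", None
        work = data.copy()
        if response_mode == "worker_cv_monomorphic_only":
            work = work[work["castes"].astype(float) == 1].copy()
    else:
        raise ValueError(f"unknown response mode {response_mode!r}")

    cols = {
        complexity_col: "complexity",
        "log10_colony_size": "colony_size",
        "log10_mating_frequency": "mating_frequency",
        "log10_queen_number": "queen_number",
    }
    # extract explicitly: vertex names may collide with raw trait columns
    work = pd.DataFrame({
        species_column: work[species_column],
        **{new: work[old].astype(float) for old, new in cols.items()},
    })
    needed = list(cols.values())
    work = work.dropna(subset=needed)
    if len(work) < 10:
        raise ValueError(f"only {len(work)} complete cases; too few for path analysis")
    ptree = tree.prune_to_taxa(list(work[species_column]))
    cov = ptree.covariance()
    order = {t: i for i, t in enumerate(cov.taxa)}
    from .treeio import match_species_to_tips

    mapping, _ = match_species_to_tips(work[species_column], cov.taxa)
    work = work.iloc[np.argsort([order[mapping[s]] for s in work[species_column]])]
    work = work.reset_index(drop=True)

    # z-score continuous vertices for standardized coefficients
    for c in needed:
        if binary is not None and c == "complexity":
            continue
        v = work[c].to_numpy(float)
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"vertex {c} has zero variance")
        work[c] = (v - v.mean()) / sd

    dags = candidate_models(complexity="complexity")
    n = len(work)
    fits = []
    bin_vertex = "complexity" if binary is not None else None
    for name, dag in dags.items():
        C, p_C, k, claims = dsep_test(dag, work, cov, binary_vertex=bin_vertex)
        q = len(dag.edges)
        fit = PathFitResult(name=name, C=C, p_C=p_C, k=k, q=q, n=n,
                            CICc=cicc(C, q, n), claims=claims)
        fit.coefficients = _path_coefficients(dag, work, cov, bin_vertex)
        fits.append(fit)
    ranking = rank_models(fits)
    averaged = average_paths(fits)
    return {
        "fits": {f.name: f for f in fits},
        "ranking": ranking,
        "averaged": averaged,
        "n": n,
        "response_mode": response_mode,
    }
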