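"""Continuous-time Markov chain machinery on trees.

This module hosts the primitives shared by the discrete-coevolution and
hidden-rate-model stages: transition matrices ``P(t) = expm(Q t)``, the
pruning (post-order) likelihood, marginal ancestral-state probabilities, an
exact Gillespie simulator along branches, and a brute-force enumeration
likelihood used as an oracle in tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.linalg import expm

from .treeio import Phylogeny, TreeIndex

__all__ = [
    "transition_matrices",
    "PruningEngine",
    "enumeration_loglik",
    "marginal_node_probabilities",
    "simulate_ctmc",
    "CTMCSimulation",
]


def validate_generator(Q: np.ndarray) -> None:
    Q = np.asarray(Q)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    off = Q - np.diag(np.diag(Q))
    if np.any(off < -1e-12):
        raise ValueError("off-diagonal rates must be non-negative")
    if np.any(np.abs(Q.sum(axis=1)) > 1e-8 * (1 + np.abs(Q).max())):
        raise ValueError("rows of a generator must sum to zero")


def transition_matrices(Q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """``P[i] = expm(Q * t[i])`` for a batch of durations.

    Uses the eigendecomposition of ``Q`` when it is well conditioned and
    falls back to scaling-and-squaring (scipy ``expm``) per unique duration
    otherwise.  Zero durations yield the identity exactly.
    """
    Q = np.asarray(Q, dtype=float)
    t = np.asarray(t, dtype=float)
    k = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        cond = np.linalg.cond(V)
        if not np.isfinite(cond) or cond > 1e8:
            raise np.linalg.LinAlgError("ill-conditioned eigenvectors")
        Vinv = np.linalg.inv(V)
        E = np.exp(np.multiply.outer(t, w))  # (m, k)
        P = np.einsum("su,mu,uv->msv", V, E, Vinv).real
    except np.linalg.LinAlgError:
        uniq, inv = np.unique(t, return_inverse=True)
        Ps = np.stack([expm(Q * ti) for ti in uniq])
        P = Ps[inv]
    np.clip(P, 0.0, None, out=P)
    # rows of expm(Qt) sum to one; renormalise away clipping residue
    P /= P.sum(axis=2, keepdims=True)
    P[t == 0.0] = np.eye(k)
    return np.ascontiguousarray(P)


def _transition_matrices_eigen(Q: np.ndarray, t: np.ndarray):
    """Fast shared-Q transition matrices via eigendecomposition.

    Returns ``None`` when the eigenvector matrix is ill conditioned (nearly
    defective Q); callers then fall back to scaling-and-squaring.
    """
    k = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(V)) or np.linalg.cond(V) > 1e8:
        return None
    E = np.exp(t[:, None] * w[None, :])        # (m, k)
    # P[m, i, j] = sum_u E[m, u] * V[i, u] * Vinv[u, j]: one flat matmul
    W = (V.T[:, :, None] * Vinv[:, None, :]).reshape(k, k * k)
    P = np.ascontiguousarray((E @ W).real.reshape(-1, k, k))
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=2, keepdims=True)
    P[t == 0.0] = np.eye(k)
    return P


@njit(cache=True)
def _expm_batch(Q, t):
    """Scaling-and-squaring Taylor expm for a batch of small matrices."""
    k = Q.shape[0]
    m = t.shape[0]
    P = np.empty((m, k, k))
    A = np.empty((k, k))
    term = np.empty((k, k))
    tmp = np.empty((k, k))
    acc = np.empty((k, k))
    for e in range(m):
        norm = 0.0
        for i in range(k):
            row = 0.0
            for j in range(k):
                A[i, j] = Q[i, j] * t[e]
                row += abs(A[i, j])
            if row > norm:
                norm = row
        s = 0
        while norm > 0.5:
            norm *= 0.5
            s += 1
        scale = 1.0 / (2.0 ** s)
        for i in range(k):
            for j in range(k):
                A[i, j] *= scale
                term[i, j] = 1.0 if i == j else 0.0
                acc[i, j] = term[i, j]
        for order in range(1, 13):
            inv = 1.0 / order
            for i in range(k):
                for j in range(k):
                    v = 0.0
                    for u in range(k):
                        v += term[i, u] * A[u, j]
                    tmp[i, j] = v * inv
            for i in range(k):
                for j in range(k):
                    term[i, j] = tmp[i, j]
                    acc[i, j] += tmp[i, j]
        for _ in range(s):
            for i in range(k):
                for j in range(k):
                    v = 0.0
                    for u in range(k):
                        v += acc[i, u] * acc[u, j]
                    tmp[i, j] = v
            for i in range(k):
                for j in range(k):
                    acc[i, j] = tmp[i, j]
        for i in range(k):
            rs = 0.0
            for j in range(k):
                if acc[i, j] < 0.0:
                    acc[i, j] = 0.0
                rs += acc[i, j]
            for j in range(k):
                P[e, i, j] = acc[i, j] / rs
    return P


@njit(cache=True)
def _loglik_fused(Q, edge_length, postorder, children_flat, children_ptr,
                  partials, root, root_prior):
    """One-call likelihood: transition matrices + pruning.

    Uses the eigendecomposition of the shared generator when it is well
    conditioned, the scaling-and-squaring batch otherwise.
    """
    k = Q.shape[0]
    m = edge_length.shape[0]
    Qc = Q.astype(np.complex128)
    w, V = np.linalg.eig(Qc)
    Vinv = np.linalg.inv(V)
    # 1-norm condition estimate of the eigenvector matrix
    n1 = 0.0
    n2 = 0.0
    finite = True
    for j in range(k):
        c1 = 0.0
        c2 = 0.0
        for i in range(k):
            a = abs(V[i, j])
            b = abs(Vinv[i, j])
            if not (np.isfinite(a) and np.isfinite(b)):
                finite = False
            c1 += a
            c2 += b
        if c1 > n1:
            n1 = c1
        if c2 > n2:
            n2 = c2
    if finite and n1 * n2 < 1e8:
        W = np.empty((k, k * k), dtype=np.complex128)
        for u in range(k):
            for i in range(k):
                for j in range(k):
                    W[u, i * k + j] = V[i, u] * Vinv[u, j]
        E = np.exp(edge_length.reshape(-1, 1) * w.reshape(1, -1))
        F = E @ W
        P = np.empty((m, k, k))
        for e in range(m):
            for i in range(k):
                s = 0.0
                for j in range(k):
                    v = F[e, i * k + j].real
                    if v < 0.0:
                        v = 0.0
                    P[e, i, j] = v
                    s += v
                for j in range(k):
                    P[e, i, j] /= s
    else:
        P = _expm_batch(Q, edge_length)
    return _prune_kernel(postorder, children_flat, children_ptr, P,
                         partials, root, root_prior)


@njit(cache=True)
def _prune_kernel(postorder, children_flat, children_ptr, P, partials, root, root_prior):
    n_internal = postorder.shape[0]
    k = partials.shape[1]
    logscale = 0.0
    for i in range(n_internal):
        v = postorder[i]
        for s in range(k):
            partials[v, s] = 1.0
        for ci in range(children_ptr[v], children_ptr[v + 1]):
            c = children_flat[ci]
            for s in range(k):
                acc = 0.0
                for u in range(k):
                    acc += P[c, s, u] * partials[c, u]
                partials[v, s] *= acc
        mx = 0.0
        for s in range(k):
            if partials[v, s] > mx:
                mx = partials[v, s]
        if mx <= 0.0:
            return -np.inf
        for s in range(k):
            partials[v, s] /= mx
        logscale += np.log(mx)
    lik = 0.0
    for s in range(k):
        lik += root_prior[s] * partials[root, s]
    if lik <= 0.0:
        return -np.inf
    return np.log(lik) + logscale


class PruningEngine:
    """Felsenstein pruning likelihood for one tree and one tip-data matrix.

    ``tip_partials`` has one row per tip (tree index order) and one column
    per state; an ambiguous tip carries 1.0 in every compatible state.
    """

    def __init__(self, tree: Phylogeny | TreeIndex, tip_partials: np.ndarray):
        self.index = tree.index if isinstance(tree, Phylogeny) else tree
        tip_partials = np.asarray(tip_partials, dtype=float)
        if tip_partials.shape[0] != self.index.n_tips:
            raise ValueError(
                f"expected {self.index.n_tips} tip rows, got {tip_partials.shape[0]}"
            )
        if np.any(tip_partials.sum(axis=1) <= 0):
            bad = np.where(tip_partials.sum(axis=1) <= 0)[0]
            raise ValueError(f"tips with no compatible state: {bad.tolist()}")
        self.tip_partials = tip_partials
        self.k = tip_partials.shape[1]
        self._partials = np.zeros((self.index.n_nodes, self.k))

    def loglik(self, Q: np.ndarray, root_prior: np.ndarray | None = None) -> float:
        ix = self.index
        if root_prior is None:
            root_prior = np.full(self.k, 1.0 / self.k)
        Q = np.ascontiguousarray(Q, dtype=np.float64)
        self._partials[: ix.n_tips] = self.tip_partials
        prior = np.asarray(root_prior, dtype=float)
        try:
            return float(_loglik_fused(
                Q, ix.edge_length, ix.postorder, ix.children_flat,
                ix.children_ptr, self._partials, ix.root, prior))
        except Exception:
            # defective eigendecompositions can raise inside the JIT path
            P = _transition_matrices_eigen(Q, ix.edge_length)
            if P is None:
                P = _expm_batch(Q, ix.edge_length)
            self._partials[: ix.n_tips] = self.tip_partials
            return float(_prune_kernel(
                ix.postorder, ix.children_flat, ix.children_ptr,
                P, self._partials, ix.root, prior))


def enumeration_loglik(
    tree: Phylogeny | TreeIndex,
    Q: np.ndarray,
    tip_partials: np.ndarray,
    root_prior: np.ndarray | None = None,
) -> float:
    """Brute-force likelihood: sum over every internal-state assignment.

    Exponential in the number of internal nodes; an independent oracle for
    the pruning algorithm on tiny trees.
    """
    ix = tree.index if isinstance(tree, Phylogeny) else tree
    k = np.asarray(Q).shape[0]
    if root_prior is None:
        root_prior = np.full(k, 1.0 / k)
    P = transition_matrices(np.asarray(Q, float), ix.edge_length)
    internals = list(ix.postorder)
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        state = dict(zip(internals, assign))
        term = root_prior[state[ix.root]]
        for v in internals:
            p = ix.parent[v]
            if p >= 0:
                term *= P[v, state[p], state[v]]
        for tip in range(ix.n_tips):
            sp = state[ix.parent[tip]]
            term *= float(P[tip, sp] @ tip_partials[tip])
        total += term
    return float(np.log(total)) if total > 0 else -np.inf


def marginal_node_probabilities(
    tree: Phylogeny | TreeIndex,
    Q: np.ndarray,
    tip_partials: np.ndarray,
    root_prior: np.ndarray | None = None,
) -> np.ndarray:
    """Marginal posterior state probabilities for every node.

    Combines post-order (below) and pre-order (above) partial likelihoods;
    rows sum to one.  Tip rows reflect observed data (degenerate for fully
    observed tips).
    """
    ix = tree.index if isinstance(tree, Phylogeny) else tree
    k = np.asarray(Q).shape[0]
    if root_prior is None:
        root_prior = np.full(k, 1.0 / k)
    root_prior = np.asarray(root_prior, float)
    P = transition_matrices(np.asarray(Q, float), ix.edge_length)

    down = np.zeros((ix.n_nodes, k))  # normalised below-partials
    down[: ix.n_tips] = tip_partials
    for v in ix.postorder:
        prod = np.ones(k)
        for c in ix.children(v):
            prod *= P[c] @ down[c]
        m = prod.max()
        if m <= 0:
            raise ValueError("data impossible under the supplied rates")
        down[v] = prod / m
    down[: ix.n_tips] /= down[: ix.n_tips].max(axis=1, keepdims=True)

    up = np.zeros((ix.n_nodes, k))  # above-partials including root prior
    up[ix.root] = root_prior
    for v in ix.preorder_nodes():
        if v == ix.root:
            continue
        p = ix.parent[v]
        sib = np.ones(k)
        for c in ix.children(p):
            if c != v:
                sib *= P[c] @ down[c]
        msg = up[p] * sib  # distribution over the parent state
        up[v] = msg @ P[v]
        m = up[v].max()
        if m > 0:
            up[v] /= m

    marg = up * down
    norm = marg.sum(axis=1, keepdims=True)
    if np.any(norm <= 0):
        raise ValueError("degenerate marginal; data impossible under the model")
    return marg / norm


@dataclass
class CTMCSimulation:
    """Result of a stochastic simulation down a tree."""

    node_states: np.ndarray           # state at every node (tips included)
    events: list[tuple[int, float, int, int]]  # (node, time-on-branch, from, to)

    def tip_states(self, n_tips: int) -> np.ndarray:
        return self.node_states[:n_tips]


def simulate_ctmc(
    tree: Phylogeny | TreeIndex,
    Q: np.ndarray,
    rng: np.random.Generator,
    root_state: int | None = None,
    root_prior: np.ndarray | None = None,
) -> CTMCSimulation:
    """Exact (Gillespie) simulation of a CTMC along every branch."""
    ix = tree.index if isinstance(tree, Phylogeny) else tree
    Q = np.asarray(Q, dtype=float)
    validate_generator(Q)
    k = Q.shape[0]
    if root_state is None:
        if root_prior is None:
            root_prior = np.full(k, 1.0 / k)
        root_state = int(rng.choice(k, p=np.asarray(root_prior) / np.sum(root_prior)))
    states = np.zeros(ix.n_nodes, dtype=np.int64)
    states[ix.root] = root_state
    events: list[tuple[int, float, int, int]] = []
    for v in ix.preorder_nodes():
        if v == ix.root:
            continue
        s = states[ix.parent[v]]
        t, T = 0.0, ix.edge_length[v]
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= T:
                break
            probs = Q[s].copy()
            probs[s] = 0.0
            new = int(rng.choice(k, p=probs / probs.sum()))
            events.append((v, t, s, new))
            s = new
        states[v] = s
    return CTMCSimulation(node_states=states, events=events)
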