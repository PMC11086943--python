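"""Binary bipartite graphs and the maximum-entropy bipartite configuration
model (BiCM).

The null model is the entropy-maximized ensemble of bipartite graphs whose
expected degree sequences equal the observed ones.  The graph probability
factorizes into independent per-link Bernoulli probabilities

    p_ia = exp(-(theta_i + eta_a)) / (1 + exp(-(theta_i + eta_a)))

with one multiplier per node, fixed by the likelihood conditions
``<k_i> = k_i*`` and ``<h_a> = h_a*``.

Solver
------
Degree-reduced fixed-point iteration on the likelihood conditions (nodes
sharing a degree provably share a multiplier, so the system is solved over
unique degrees), with a damped least-squares fallback if the fixed point
stalls.  Degree-0 and full-degree nodes are peeled off before solving and
reinstated with p in {0, 1}: that is the exact limit of the model and avoids
divergent multipliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit

logger = logging.getLogger("echonet.bicm")


class ConvergenceError(RuntimeError):
    """Solver failed to satisfy the likelihood conditions within budget."""


@dataclass
class BipartiteGraph:
    """A binary bipartite graph described by its biadjacency matrix.

    ``biadjacency[i, a]`` is 1 iff top node ``top_nodes[i]`` links bottom
    node ``bottom_nodes[a]``.
    """

    top_nodes: list
    bottom_nodes: list
    biadjacency: np.ndarray

    def __post_init__(self) -> None:
        self.biadjacency = np.asarray(self.biadjacency)
        nt, nb = self.biadjacency.shape
        if nt != len(self.top_nodes) or nb != len(self.bottom_nodes):
            raise ValueError(
                f"biadjacency shape {self.biadjacency.shape} does not match node lists "
                f"({len(self.top_nodes)}, {len(self.bottom_nodes)})"
            )
        vals = np.unique(self.biadjacency)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("biadjacency must be binary (entries in {0, 1})")
        self.biadjacency = self.biadjacency.astype(np.int8)

    @property
    def n_top(self) -> int:
        return len(self.top_nodes)

    @property
    def n_bottom(self) -> int:
        return len(self.bottom_nodes)

    @property
    def top_degrees(self) -> np.ndarray:
        """k_i = row sums."""
        return self.biadjacency.sum(axis=1).astype(np.int64)

    @property
    def bottom_degrees(self) -> np.ndarray:
        """h_a = column sums."""
        return self.biadjacency.sum(axis=0).astype(np.int64)

    @property
    def n_links(self) -> int:
        return int(self.biadjacency.sum())

    @classmethod
    def from_edges(cls, edges, top_nodes=None, bottom_nodes=None) -> "BipartiteGraph":
        """Build from (top_id, bottom_id) pairs; node order is first-seen
        unless explicit node lists are given."""
        edges = list(edges)
        if top_nodes is None:
            top_nodes = list(dict.fromkeys(t for t, _ in edges))
        if bottom_nodes is None:
            bottom_nodes = list(dict.fromkeys(b for _, b in edges))
        ti = {t: i for i, t in enumerate(top_nodes)}
        bi = {b: i for i, b in enumerate(bottom_nodes)}
        B = np.zeros((len(top_nodes), len(bottom_nodes)), dtype=np.int8)
        for t, b in edges:
            B[ti[t], bi[b]] = 1
        return cls(top_nodes=list(top_nodes), bottom_nodes=list(bottom_nodes), biadjacency=B)

    def to_edges(self) -> list[tuple]:
        rows, cols = np.nonzero(self.biadjacency)
        return [(self.top_nodes[i], self.bottom_nodes[a]) for i, a in zip(rows, cols)]


@dataclass
class BiCMModel:
    """Fitted BiCM: per-node Lagrange multipliers and per-pair link
    probabilities.

    Multipliers of peeled degenerate nodes (degree 0 or full) are NaN — their
    exact-limit probabilities (0 or 1) are stored directly in ``p``.
    """

    theta: np.ndarray
    eta: np.ndarray
    p: np.ndarray
    residual: float
    n_iter: int
    method: str = "fixed-point"
    top_nodes: list = field(default_factory=list)
    bottom_nodes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "theta": self.theta.tolist(),
            "eta": self.eta.tolist(),
            "residual": self.residual,
            "n_iter": self.n_iter,
            "method": self.method,
            "top_nodes": list(self.top_nodes),
            "bottom_nodes": list(self.bottom_nodes),
        }


def _peel_degenerate(B: np.ndarray):
    """Iteratively remove degree-0 and full-degree rows/columns.

    Returns (p, active_rows, active_cols, k_core, h_core) where ``p`` already
    holds the exact-limit probabilities for every peeled node.
    """
    nt, nb = B.shape
    p = np.full((nt, nb), np.nan)
    row_active = np.ones(nt, dtype=bool)
    col_active = np.ones(nb, dtype=bool)
    k = B.sum(axis=1).astype(float)
    h = B.sum(axis=0).astype(float)

    changed = True
    while changed:
        changed = False
        n_cols = int(col_active.sum())
        for i in np.nonzero(row_active)[0]:
            if k[i] == 0:
                p[i, col_active] = 0.0
                row_active[i] = False
                changed = True
            elif k[i] == n_cols and n_cols > 0:
                p[i, col_active] = 1.0
                h[col_active] -= 1.0
                row_active[i] = False
                changed = True
        n_rows = int(row_active.sum())
        for a in np.nonzero(col_active)[0]:
            if h[a] == 0:
                p[row_active, a] = 0.0
                col_active[a] = False
                changed = True
            elif h[a] == n_rows and n_rows > 0:
                p[row_active, a] = 1.0
                k[row_active] -= 1.0
                col_active[a] = False
                changed = True
    return p, row_active, col_active, k[row_active], h[col_active]


def _reduced_residual(x: np.ndarray, y: np.ndarray, cnt_k: np.ndarray, cnt_h: np.ndarray,
                      ku: np.ndarray, hu: np.ndarray) -> float:
    P = np.outer(x, y)
    P = P / (1.0 + P)
    rk = np.abs(P @ cnt_h.astype(float) - ku)
    rh = np.abs(P.T @ cnt_k.astype(float) - hu)
    return float(max(rk.max(initial=0.0), rh.max(initial=0.0)))


def _solve_core(k: np.ndarray, h: np.ndarray, tol: float, max_iter: int):
    """Solve the likelihood conditions on the non-degenerate core.

    Works over unique degree classes: nodes with equal degree share a
    multiplier, which both shrinks the system and guarantees bit-identical
    multipliers for equal degrees.
    """
    ku, inv_k, cnt_k = np.unique(k, return_inverse=True, return_counts=True)
    hu, inv_h, cnt_h = np.unique(h, return_inverse=True, return_counts=True)
    L = k.sum()
    x = ku / np.sqrt(L)
    y = hu / np.sqrt(L)
    ch = cnt_h.astype(float)
    ck = cnt_k.astype(float)

    n_iter = 0
    method = "fixed-point"
    res = np.inf
    for n_iter in range(1, max_iter + 1):
        denom_x = (y[None, :] / (1.0 + np.outer(x, y))) @ ch
        x = ku / denom_x
        denom_y = (x[None, :] / (1.0 + np.outer(y, x))) @ ck
        y = hu / denom_y
        if n_iter % 10 == 0 or n_iter <= 5:
            res = _reduced_residual(x, y, cnt_k, cnt_h, ku, hu)
            if res <= tol:
                break
    else:
        res = _reduced_residual(x, y, cnt_k, cnt_h, ku, hu)

    if res > tol:
        # damped-Newton fallback on log-multipliers (trust-region LSQ)
        method = "fixed-point+lsq"

        def residuals(z):
            xx = np.exp(z[: len(ku)])
            yy = np.exp(z[len(ku):])
            P = np.outer(xx, yy)
            P = P / (1.0 + P)
            return np.concatenate([P @ ch - ku, P.T @ ck - hu])

        z0 = np.log(np.concatenate([x, y]))
        sol = optimize.least_squares(residuals, z0, method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15)
        x = np.exp(sol.x[: len(ku)])
        y = np.exp(sol.x[len(ku):])
        res = _reduced_residual(x, y, cnt_k, cnt_h, ku, hu)
        if res > tol:
            raise ConvergenceError(
                f"BiCM solver did not reach tol={tol:g} in {max_iter} iterations "
                f"(+fallback); max degree residual {res:.3e}"
            )
    return x[inv_k], y[inv_h], res, n_iter, method


def fit_bicm(g: BipartiteGraph, tol: float = 1e-8, max_iter: int = 10_000) -> BiCMModel:
    """Fit the BiCM to a bipartite graph.

    The returned model satisfies ``|sum_a p_ia - k_i*| <= tol`` for every top
    node and symmetrically for every bottom node.  Nodes with equal degree
    receive bit-identical multipliers; degree-0 / full-degree nodes are
    handled by exact pre-reduction.

    Raises
    ------
    ConvergenceError
        If the residual target is not met within ``max_iter`` (plus the
        least-squares fallback).
    ValueError
        For an empty graph object or non-positive ``tol``.
    """
    if g.n_top == 0 or g.n_bottom == 0:
        raise ValueError("cannot fit BiCM on a graph with an empty layer")
    if tol <= 0:
        raise ValueError("tol must be positive")

    B = g.biadjacency
    p, row_active, col_active, k_core, h_core = _peel_degenerate(B)
    nt, nb = B.shape
    theta = np.full(nt, np.nan)
    eta = np.full(nb, np.nan)

    if k_core.size and h_core.size:
        x, y, res, n_iter, method = _solve_core(k_core, h_core, tol, max_iter)
        theta[row_active] = -np.log(x)
        eta[col_active] = -np.log(y)
        core = expit(-(theta[row_active][:, None] + eta[col_active][None, :]))
        p[np.ix_(row_active, col_active)] = core
    else:
        res, n_iter, method = 0.0, 0, "degenerate-only"

    assert not np.isnan(p).any()
    return BiCMModel(
        theta=theta,
        eta=eta,
        p=p,
        residual=res,
        n_iter=n_iter,
        method=method,
        top_nodes=list(g.top_nodes),
        bottom_nodes=list(g.bottom_nodes),
    )


def log_likelihood(model: BiCMModel, g: BipartiteGraph) -> float:
    """Bernoulli log-likelihood of a graph under the model.

    ``sum_ia [b_ia ln p_ia + (1 - b_ia) ln(1 - p_ia)]`` with ``0 ln 0 := 0``;
    an impossible graph (b=1 where p=0 or b=0 where p=1) gives ``-inf``.
    """
    if model.p.shape != g.biadjacency.shape:
        raise ValueError(f"shape mismatch: model {model.p.shape} vs graph {g.biadjacency.shape}")
    B = g.biadjacency.astype(float)
    p = model.p
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(B == 1, np.log(p, out=np.full_like(p, -np.inf), where=p > 0), 0.0)
        term0 = np.where(B == 0, np.log1p(-np.minimum(p, 1.0), out=np.full_like(p, -np.inf), where=p < 1), 0.0)
    total = term1.sum() + term0.sum()
    return float(total)


def graph_probability(model: BiCMModel, g: BipartiteGraph) -> float:
    """P(G) under the factorized ensemble (exp of the log-likelihood)."""
    return float(np.exp(log_likelihood(model, g)))


def sample_graph(model: BiCMModel, seed: int) -> BipartiteGraph:
    """Draw one graph from the ensemble: independent Bernoulli(p_ia) entries."""
    rng = np.random.default_rng(seed)
    B = (rng.random(model.p.shape) < model.p).astype(np.int8)
    return BipartiteGraph(
        top_nodes=list(model.top_nodes) or list(range(model.p.shape[0])),
        bottom_nodes=list(model.bottom_nodes) or list(range(model.p.shape[1])),
        biadjacency=B,
    )
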