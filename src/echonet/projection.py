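"""Statistically validated monopartite projections of bipartite graphs.

For every unordered pair of nodes on the projected layer, the number of
common neighbors across the opposite layer (the V-motif count) is compared
with its distribution under the fitted null model.  Under the factorized
ensemble, the pair (i, j) co-occurs on opposite-layer node a with
probability ``p_ia * p_ja`` independently across a, so the null count is
Poisson-binomial.  A one-tailed upper p-value P(V >= V*) is computed exactly
by dynamic-programming convolution, and the family of all C(N, 2) pairs is
filtered with the Benjamini-Hochberg FDR procedure; surviving pairs become
edges of the validated projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from echonet.bicm import BiCMModel, BipartiteGraph

logger = logging.getLogger("echonet.projection")


@dataclass
class CooccurrenceTable:
    """Observed co-occurrence counts (and p-values, once computed) for all
    unordered pairs on one layer."""

    layer: str
    nodes: list
    pairs: list[tuple[int, int]]          # index pairs into ``nodes``
    v_star: np.ndarray                    # observed common-neighbor counts
    pvalues: np.ndarray | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class ValidatedProjection:
    """Result of the FDR-filtered projection onto one layer."""

    layer: str
    alpha: float
    n_tests: int
    threshold: float | None               # largest accepted p-value, None if no rejection
    edges: list[tuple]                    # (node_id, node_id, v_star, pvalue)
    graph: nx.Graph = field(default_factory=nx.Graph)
    table: CooccurrenceTable | None = None

    @property
    def validated_nodes(self) -> set:
        return {n for n in self.graph.nodes if self.graph.degree(n) > 0}


def count_vmotifs(g: BipartiteGraph, layer: str = "top") -> CooccurrenceTable:
    """Count common neighbors V*_ij for every unordered pair on ``layer``."""
    if layer not in ("top", "bottom"):
        raise ValueError(f"layer must be 'top' or 'bottom', got {layer!r}")
    B = g.biadjacency.astype(np.int64)
    if layer == "top":
        nodes, M = g.top_nodes, B @ B.T
    else:
        nodes, M = g.bottom_nodes, B.T @ B
    n = len(nodes)
    if n < 2:
        raise ValueError(f"layer {layer!r} has {n} nodes; need at least 2 to project")
    iu, ju = np.triu_indices(n, k=1)
    pairs = list(zip(iu.tolist(), ju.tolist()))
    return CooccurrenceTable(layer=layer, nodes=list(nodes), pairs=pairs, v_star=M[iu, ju])


def poisson_binomial_sf(probs, observed: int) -> float:
    """Exact upper-tail P(V >= observed) for a sum of independent Bernoullis.

    Dynamic-programming convolution over the first ``observed`` mass points,
    O(len(probs) * observed): the mass at counts >= observed is never tracked
    explicitly, so ``sf = 1 - sum(dp)`` at the end.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1:
        raise ValueError("probs must be a 1-D sequence")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if observed != int(observed) or observed < 0:
        raise ValueError(f"observed must be a non-negative integer, got {observed!r}")
    observed = int(observed)
    if observed == 0:
        return 1.0
    if observed > len(probs):
        return 0.0
    # dp[j] = P(V = j over processed trials), tracked for j < observed only
    dp = np.zeros(observed)
    dp[0] = 1.0
    for p in probs:
        dp[1:] = dp[1:] * (1.0 - p) + dp[:-1] * p
        dp[0] *= 1.0 - p
    return float(min(1.0, max(0.0, 1.0 - dp.sum())))


def bh_select(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, float | None]:
    """Benjamini-Hochberg rejection over a family of m p-values.

    Rejects every hypothesis with ``p <= p_(khat)`` where
    ``khat = max{k : p_(k) <= k * alpha / m}`` on the sorted p-values.

    Returns (boolean rejection mask aligned with the input, threshold
    p-value or None when nothing is rejected).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("pvalues must be nonempty")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    ks = np.nonzero(sorted_p <= (np.arange(1, m + 1) * alpha / m))[0]
    if ks.size == 0:
        return np.zeros(m, dtype=bool), None
    threshold = float(sorted_p[ks[-1]])
    return p <= threshold, threshold


def validate_projection(
    g: BipartiteGraph,
    model: BiCMModel,
    layer: str = "top",
    alpha: float = 0.05,
) -> ValidatedProjection:
    """Project ``g`` onto ``layer``, keeping only pairs whose co-occurrence
    count is significant under the fitted null model at FDR level ``alpha``.

    The multiple-testing family is *all* C(N, 2) unordered pairs on the
    layer; pairs with V* = 0 get p = 1 and can never be rejected, but they
    count toward m.
    """
    if model.p.shape != g.biadjacency.shape:
        raise ValueError("model was not fitted on this graph (shape mismatch)")
    table = count_vmotifs(g, layer)
    P = model.p if layer == "top" else model.p.T

    pvals = np.ones(table.n_pairs)
    for idx, (i, j) in enumerate(table.pairs):
        v = int(table.v_star[idx])
        if v == 0:
            continue  # P(V >= 0) = 1 by definition
        pvals[idx] = poisson_binomial_sf(P[i] * P[j], v)
    table.pvalues = pvals

    reject, threshold = bh_select(pvals, alpha)
    graph = nx.Graph()
    edges = []
    for idx, (i, j) in enumerate(table.pairs):
        if reject[idx]:
            u, v_node = table.nodes[i], table.nodes[j]
            graph.add_edge(u, v_node, weight=1.0, pvalue=float(pvals[idx]))
            edges.append((u, v_node, int(table.v_star[idx]), float(pvals[idx])))
    logger.info(
        "validate_projection(%s): %d/%d pairs validated at alpha=%g (threshold=%s)",
        layer, len(edges), table.n_pairs, alpha, threshold,
    )
    return ValidatedProjection(
        layer=layer,
        alpha=alpha,
        n_tests=table.n_pairs,
        threshold=threshold,
        edges=edges,
        graph=graph,
        table=table,
    )
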