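"""Community detection and label propagation.

Louvain is node-order dependent, so the partition is chosen as the best of
``n_shuffles`` seeded restarts on shuffled node orders (maximal modularity,
ties broken by lowest restart index).  Label propagation extends community
labels from a labeled seed set (the verified users) to the rest of a retweet
network with a two-phase weighted majority rule: a node first listens to its
seed-labeled neighbors; only if it has none does it listen to already-labeled
non-seed neighbors.  Ties are broken uniformly at random under the run seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

logger = logging.getLogger("echonet.community")


@dataclass
class Partition:
    membership: dict
    modularity: float
    n_shuffles: int
    winning_index: int

    def communities(self) -> dict:
        """community id -> sorted member list."""
        out: dict = {}
        for node, cid in self.membership.items():
            out.setdefault(cid, []).append(node)
        return {cid: sorted(members, key=str) for cid, members in out.items()}


def modularity(g: nx.Graph, membership: dict, weight: str = "weight") -> float:
    """Newman-Girvan weighted modularity at resolution 1.

    Q = sum_c [ w_in_c / W - (s_c / 2W)^2 ] with W the total edge weight,
    w_in_c the intra-community weight and s_c the community's weighted
    degree sum (self-loops counted twice in s_c, once in w_in_c per
    convention of weighted degree).
    """
    missing = [n for n in g.nodes if n not in membership]
    if missing:
        raise ValueError(f"membership missing {len(missing)} nodes (e.g. {missing[:3]})")
    m = g.size(weight=weight)  # self-loops counted once
    if m == 0:
        return 0.0
    w_in: dict = {}
    for u, v, d in g.edges(data=True):
        if membership[u] == membership[v]:
            w_in[membership[u]] = w_in.get(membership[u], 0.0) + d.get(weight, 1.0)
    deg: dict = {}
    for n in g.nodes:  # weighted degree counts self-loops twice
        c = membership[n]
        deg[c] = deg.get(c, 0.0) + g.degree(n, weight=weight)
    q = 0.0
    for c in set(membership.values()):
        q += w_in.get(c, 0.0) / m - (deg.get(c, 0.0) / (2.0 * m)) ** 2
    return q


def louvain_best_of(g: nx.Graph, n_shuffles: int = 1000, seed: int = 0) -> Partition:
    """Best-of-N Louvain: run the algorithm ``n_shuffles`` times on shuffled
    node orders under deterministically derived sub-seeds and keep the
    partition with the greatest modularity (ties -> lowest restart index).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot detect communities on an empty graph")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if g.number_of_edges() == 0:
        logger.warning("louvain_best_of: graph has no edges; every node is its own community")
        membership = {n: i for i, n in enumerate(sorted(g.nodes, key=str))}
        return Partition(membership=membership, modularity=0.0, n_shuffles=n_shuffles, winning_index=-1)

    sub_seeds = derive_sub_seeds(seed, n_shuffles)
    best: Partition | None = None
    for idx, sub_seed in enumerate(sub_seeds):
        membership = _louvain_once(g, sub_seed)
        q = modularity(g, membership)
        if best is None or q > best.modularity:
            best = Partition(membership=membership, modularity=q, n_shuffles=n_shuffles, winning_index=idx)
    assert best is not None
    return best


def derive_sub_seeds(seed: int, n_shuffles: int) -> list[int]:
    """The deterministic restart sub-seeds used by :func:`louvain_best_of`."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n_shuffles)]


def _louvain_once(g: nx.Graph, sub_seed: int) -> dict:
    """One Louvain run on a shuffled node order under one sub-seed."""
    order = list(g.nodes)
    np.random.default_rng(sub_seed).shuffle(order)
    h = g.__class__()
    h.add_nodes_from(order)
    h.add_edges_from(g.edges(data=True))
    comms = nx.community.louvain_communities(h, weight="weight", seed=sub_seed)
    return {n: cid for cid, members in enumerate(comms) for n in members}


def propagate_labels(
    g: nx.Graph,
    seed_labels: dict,
    seed: int = 0,
    max_iter: int = 1000,
    weighted: bool = True,
) -> dict:
    """Two-phase majority label propagation over an undirected network.

    Seed-labeled nodes keep their labels permanently.  Each sweep visits the
    unlabeled-at-seed nodes in a seeded random order; a node takes the
    weighted-majority label of its seed neighbors, or — if it has no seed
    neighbor — of its currently labeled non-seed neighbors.  Sweeps repeat
    until a full pass changes nothing or ``max_iter`` is hit (warned).
    Nodes never reached stay out of the returned mapping.
    """
    if not seed_labels:
        raise ValueError("seed_labels must be nonempty")
    rng = np.random.default_rng(seed)
    weight_of = (lambda d: d.get("weight", 1.0)) if weighted else (lambda d: 1.0)

    labels = {n: lab for n, lab in seed_labels.items() if n in g}
    seeds = set(labels)
    free = [n for n in g.nodes if n not in seeds]

    def majority(votes: dict):
        if not votes:
            return None
        top = max(votes.values())
        winners = sorted([lab for lab, w in votes.items() if w == top], key=str)
        if len(winners) == 1:
            return winners[0]
        return winners[int(rng.integers(len(winners)))]

    for iteration in range(max_iter):
        changed = False
        order = list(free)
        rng.shuffle(order)
        for node in order:
            seed_votes: dict = {}
            other_votes: dict = {}
            for nbr in g.neighbors(node):
                if nbr == node:
                    continue
                w = weight_of(g[node][nbr])
                if nbr in seeds:
                    seed_votes[labels[nbr]] = seed_votes.get(labels[nbr], 0.0) + w
                elif nbr in labels:
                    other_votes[labels[nbr]] = other_votes.get(labels[nbr], 0.0) + w
            new = majority(seed_votes) if seed_votes else majority(other_votes)
            if new is not None and labels.get(node) != new:
                labels[node] = new
                changed = True
        if not changed:
            break
    else:
        logger.warning("propagate_labels: no convergence within %d sweeps", max_iter)
    return labels
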