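"""Pipeline orchestration: the two detection paths and their intersection.

Path 1 (discursive communities, DiCo): verified/unverified retweet bipartite
network -> BiCM -> validated projection on the verified layer -> best-of-N
Louvain -> label propagation over the undirected retweet network.

Path 2 (news-engagement communities, NEC): user/URL bipartite network ->
BiCM -> validated user-layer projection -> best-of-N Louvain; community ids
are ranked by descending size.

Echo chambers: groups of users that share a NEC and a DiCo and form a weakly
connected component of the retweet network (by default the component is
computed on the subgraph induced by the co-members themselves; the
``dico_paths`` mode allows indirect connections through any same-DiCo user).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from echonet.bicm import BipartiteGraph, fit_bicm
from echonet.community import Partition, louvain_best_of, propagate_labels
from echonet.io import Dataset, TrustLabelTable, write_outputs
from echonet.misinfo import canonicalize_url, tally_trust
from echonet.projection import ValidatedProjection, validate_projection

logger = logging.getLogger("echonet.pipeline")


# --------------------------------------------------------------------------
# network construction
# --------------------------------------------------------------------------

@dataclass
class RetweetNetwork:
    """Directed weighted retweet graph: edge (a -> b, w) means user b
    retweeted user a w times (content flows a -> b)."""

    graph: nx.DiGraph

    @property
    def total_weight(self) -> int:
        return int(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def undirected(self) -> nx.Graph:
        """Undirected simple view; antiparallel weights are summed."""
        und = nx.Graph()
        und.add_nodes_from(self.graph.nodes)
        for a, b, d in self.graph.edges(data=True):
            w = d["weight"]
            if und.has_edge(a, b):
                und[a][b]["weight"] += w
            else:
                und.add_edge(a, b, weight=w)
        return und


def build_retweet_network(d: Dataset) -> RetweetNetwork:
    """One directed edge per (retweeted author, retweeter) pair, weighted by
    retweet multiplicity; original posts contribute no edges but their
    authors are present as (possibly isolated) nodes."""
    g = nx.DiGraph()
    for p in d.posts:
        g.add_node(p.author_id)
        if p.retweeted_author_id is not None:
            a, b = p.retweeted_author_id, p.author_id
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return RetweetNetwork(graph=g)


def build_verified_bipartite(d: Dataset) -> BipartiteGraph:
    """Binary bipartite network of verified (top) vs unverified (bottom)
    users, linked iff any retweet connects them in either role.

    Retweets between two verified or two unverified users are excluded from
    this network (logged); they still count in the retweet network.
    """
    vmap = d.verified_map()
    links: set[tuple[str, str]] = set()
    excluded = 0
    for p in d.posts:
        if p.retweeted_author_id is None:
            continue
        a, b = p.author_id, p.retweeted_author_id
        va, vb = vmap.get(a, False), vmap.get(b, False)
        if va == vb:
            excluded += 1
            continue
        links.add((a, b) if va else (b, a))
    top = sorted({u for u, v in vmap.items() if v})
    bottom = sorted({u for u, v in vmap.items() if not v})
    if not top or not bottom:
        raise ValueError(
            f"need both verified and unverified users (found {len(top)} verified, "
            f"{len(bottom)} unverified)"
        )
    if excluded:
        logger.info("build_verified_bipartite: excluded %d same-layer retweets", excluded)
    return BipartiteGraph.from_edges(links, top_nodes=top, bottom_nodes=bottom)


def build_user_url_bipartite(d: Dataset, url_map: dict[str, str] | None = None) -> BipartiteGraph:
    """Binary bipartite network of users (top) vs canonical URLs (bottom):
    a link iff the user ever shared the URL (in a tweet or retweet)."""
    links: set[tuple[str, str]] = set()
    dropped = 0
    for p in d.posts:
        for raw in dict.fromkeys(p.urls):
            canon = canonicalize_url(raw, url_map)
            if canon is None:
                dropped += 1
                continue
            links.add((p.author_id, canon[0]))
    if not links:
        raise ValueError("dataset has no parseable URL-bearing posts; cannot build user-URL network")
    if dropped:
        logger.warning("build_user_url_bipartite: dropped %d unparseable URLs", dropped)
    top = sorted({u for u, _ in links})
    bottom = sorted({x for _, x in links})
    logger.info("build_user_url_bipartite: %d users x %d URLs, %d links", len(top), len(bottom), len(links))
    return BipartiteGraph.from_edges(links, top_nodes=top, bottom_nodes=bottom)


# --------------------------------------------------------------------------
# the two detection paths
# --------------------------------------------------------------------------

def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic sub-seed derivation from one master seed."""
    return [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class DiCoAssignment:
    labels: dict[str, object]                      # user -> DiCo label; absent = unlabeled
    verified_partition: Partition | None
    projection: ValidatedProjection | None
    minor_labels: set = field(default_factory=set)  # communities below the size threshold

    def tallies(self, d: Dataset, url_only: bool = False) -> dict:
        """Per-DiCo users / tweets / retweets (optionally URL-bearing only)."""
        users: Counter = Counter()
        tweets: Counter = Counter()
        retweets: Counter = Counter()
        for u, lab in self.labels.items():
            users[str(lab)] += 1
        for p in d.posts:
            if url_only and not p.urls:
                continue
            lab = self.labels.get(p.author_id)
            lab = "__none__" if lab is None else str(lab)
            (retweets if p.is_retweet else tweets)[lab] += 1
        return {"users": dict(users), "tweets": dict(tweets), "retweets": dict(retweets)}


def detect_dico(
    d: Dataset,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    minor_fraction: float = 0.01,
) -> DiCoAssignment:
    """Detect discursive communities.

    Fits the null model on the verified/unverified retweet bipartite
    network, validates the verified-layer projection, partitions it with
    best-of-N Louvain, and propagates the community labels to all users over
    the undirected retweet network.  Communities holding fewer than
    ``minor_fraction`` of labeled users are flagged minor (kept, not
    dropped).
    """
    s_louvain, s_prop = _spawn_seeds(seed, 2)
    bip = build_verified_bipartite(d)
    model = fit_bicm(bip)
    proj = validate_projection(bip, model, layer="top", alpha=alpha)
    if proj.graph.number_of_edges() == 0:
        logger.warning("detect_dico: empty validated projection; no users are labeled")
        return DiCoAssignment(labels={}, verified_partition=None, projection=proj)
    part = louvain_best_of(proj.graph, n_shuffles=n_shuffles, seed=s_louvain)
    rt = build_retweet_network(d)
    labels = propagate_labels(rt.undirected(), part.membership, seed=s_prop)
    sizes = Counter(labels.values())
    n_labeled = sum(sizes.values())
    minor = {lab for lab, c in sizes.items() if c < minor_fraction * n_labeled}
    if minor:
        logger.info("detect_dico: %d minor communities (<%g of labeled users)", len(minor), minor_fraction)
    return DiCoAssignment(labels=labels, verified_partition=part, projection=proj, minor_labels=minor)


@dataclass
class NECAssignment:
    nec: dict[str, int]                            # validated user -> NEC id (0 = largest)
    partition: Partition | None
    projection: ValidatedProjection | None

    @property
    def validated_users(self) -> set[str]:
        return set(self.nec)

    def sizes(self) -> dict[int, int]:
        return dict(Counter(self.nec.values()))


def detect_nec(
    d: Dataset,
    alpha: float = 0.05,
    n_shuffles: int = 1000,
    seed: int = 0,
    url_map: dict[str, str] | None = None,
) -> NECAssignment:
    """Detect news-engagement communities on the validated user-layer
    projection of the user/URL bipartite network.  NEC ids are assigned by
    descending community size (ties by smallest member id)."""
    (s_louvain,) = _spawn_seeds(seed, 1)
    bip = build_user_url_bipartite(d, url_map)
    model = fit_bicm(bip)
    proj = validate_projection(bip, model, layer="top", alpha=alpha)
    if proj.graph.number_of_edges() == 0:
        logger.warning("detect_nec: empty validated projection; no NECs")
        return NECAssignment(nec={}, partition=None, projection=proj)
    part = louvain_best_of(proj.graph, n_shuffles=n_shuffles, seed=s_louvain)
    comms = part.communities()
    ranked = sorted(comms.items(), key=lambda kv: (-len(kv[1]), str(kv[1][0])))
    nec = {u: rank for rank, (_, members) in enumerate(ranked) for u in members}
    return NECAssignment(nec=nec, partition=part, projection=proj)


# --------------------------------------------------------------------------
# echo chambers
# --------------------------------------------------------------------------

@dataclass
class EchoChamber:
    id: str
    nec_id: int
    dico: object
    members: frozenset[str]
    clustering: float
    rt_generated: int = 0
    rt_received: int = 0

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "nec_id": self.nec_id,
            "dico": self.dico,
            "members": sorted(self.members),
            "size": len(self.members),
            "clustering": self.clustering,
            "rt_generated": self.rt_generated,
            "rt_received": self.rt_received,
        }


def average_clustering(rt: "RetweetNetwork | nx.Graph", nodes) -> float:
    """Mean local clustering coefficient over ``nodes`` on the undirected
    simple view (no self-loops, weights ignored); degree<2 nodes count 0."""
    nodes = list(nodes)
    if not nodes:
        raise ValueError("cannot average clustering over an empty node set")
    g = rt.undirected() if isinstance(rt, RetweetNetwork) else nx.Graph(rt)
    g.remove_edges_from(nx.selfloop_edges(g))
    present = [n for n in nodes if n in g]
    cc = nx.clustering(g, present)
    return float(sum(cc.values()) / len(nodes))


def detect_echo_chambers(
    dico: DiCoAssignment,
    nec: NECAssignment,
    rt: RetweetNetwork,
    connectivity_mode: str = "nec_induced",
) -> tuple[list[EchoChamber], set[str]]:
    """Intersect NEC and DiCo membership with retweet connectivity.

    For each (NEC, DiCo) group of co-members, weakly connected components
    are taken on the retweet subgraph induced by the co-members themselves
    (``nec_induced``, default) or with paths allowed through any same-DiCo
    user (``dico_paths``).  Every component with >= 2 members becomes an
    echo chamber inheriting the NEC id (suffixed when a NEC splits).
    Returns (chambers, excluded co-members that ended in no chamber).

    Chamber clustering is measured on the undirected retweet subgraph
    restricted to the host DiCo (the discourse the chamber lives in).
    """
    if connectivity_mode not in ("nec_induced", "dico_paths"):
        raise ValueError(f"unknown connectivity_mode {connectivity_mode!r}")
    und = rt.undirected()
    dgraph = rt.graph
    chambers: list[EchoChamber] = []
    excluded: set[str] = set()

    groups: dict[tuple[int, object], list[str]] = {}
    for u, nid in nec.nec.items():
        lab = dico.labels.get(u)
        if lab is None:
            excluded.add(u)
            continue
        groups.setdefault((nid, lab), []).append(u)

    dico_members: dict[object, set[str]] = {}
    for u, lab in dico.labels.items():
        dico_members.setdefault(lab, set()).add(u)

    for (nid, lab), members in sorted(groups.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        member_set = set(members)
        if connectivity_mode == "nec_induced":
            sub = und.subgraph(member_set)
            comps = [set(c) for c in nx.connected_components(sub)]
        else:
            carrier = und.subgraph(dico_members[lab] | member_set)
            comps = [set(c) & member_set for c in nx.connected_components(carrier)]
            comps = [c for c in comps if c]
        comps = sorted((c for c in comps if len(c) >= 2), key=lambda c: (-len(c), min(c)))
        excluded.update(member_set - set().union(*comps) if comps else member_set)
        dico_view = und.subgraph(dico_members[lab])
        for k, comp in enumerate(comps):
            cid = str(nid) if len(comps) == 1 else f"{nid}_{k}"
            generated = sum(d["weight"] for a, b, d in dgraph.out_edges(comp, data=True))
            received = sum(d["weight"] for a, b, d in dgraph.in_edges(comp, data=True))
            chambers.append(EchoChamber(
                id=cid,
                nec_id=nid,
                dico=lab,
                members=frozenset(comp),
                clustering=average_clustering(dico_view, comp),
                rt_generated=int(generated),
                rt_received=int(received),
            ))
    logger.info("detect_echo_chambers: %d chambers, %d excluded users", len(chambers), len(excluded))
    return chambers, excluded


def aggregate_flow(
    rt: RetweetNetwork,
    chambers: list[EchoChamber],
    weight_min: int = 0,
    dico_users: set[str] | None = None,
) -> nx.DiGraph:
    """Aggregate the retweet network over echo chambers.

    Nodes are chamber ids plus the sentinel ``-1`` for users (of the host
    DiCo, when ``dico_users`` is given, otherwise all remaining retweet-graph
    users) not in any chamber.  Edge (g1 -> g2, w): content authored in g1
    was retweeted w times by users of g2.  Self-loops are kept; edges lighter
    than ``weight_min`` are dropped.
    """
    group_of: dict[str, object] = {}
    for ch in chambers:
        for u in ch.members:
            group_of[u] = ch.id
    pool = dico_users if dico_users is not None else set(rt.graph.nodes)
    for u in pool:
        group_of.setdefault(u, -1)

    agg = nx.DiGraph()
    agg.add_nodes_from({g for g in group_of.values()})
    for a, b, d in rt.graph.edges(data=True):
        ga, gb = group_of.get(a), group_of.get(b)
        if ga is None or gb is None:
            continue
        if agg.has_edge(ga, gb):
            agg[ga][gb]["weight"] += d["weight"]
        else:
            agg.add_edge(ga, gb, weight=d["weight"])
    if weight_min > 0:
        drop = [(a, b) for a, b, d in agg.edges(data=True) if d["weight"] < weight_min]
        agg.remove_edges_from(drop)
    return agg


# --------------------------------------------------------------------------
# end-to-end run
# --------------------------------------------------------------------------

def run_pipeline(
    d: Dataset,
    alpha: float = 0.05,
    n_shuffles: int = 1000,
    seed: int = 0,
    connectivity_mode: str = "nec_induced",
    url_map: dict[str, str] | None = None,
    trust_labels: TrustLabelTable | None = None,
    weight_min: int = 0,
    out_dir=None,
) -> dict:
    """Run both detection paths, extract echo chambers and build the report.

    Returns the report dict; when ``out_dir`` is given, graphs and reports
    are also written there (GraphML/CSV/JSON plus a checksum manifest).
    """
    s_dico, s_nec = _spawn_seeds(seed, 2)
    rt = build_retweet_network(d)
    dico = detect_dico(d, n_shuffles=n_shuffles, alpha=alpha, seed=s_dico)
    nec = detect_nec(d, alpha=alpha, n_shuffles=n_shuffles, seed=s_nec, url_map=url_map)
    chambers, excluded = detect_echo_chambers(dico, nec, rt, connectivity_mode)

    host_dicos = {ch.dico for ch in chambers}
    flow = None
    if chambers:
        host = sorted(host_dicos, key=str)[0]
        host_users = {u for u, lab in dico.labels.items() if lab == host}
        flow = aggregate_flow(rt, [c for c in chambers if c.dico == host], weight_min, host_users)

    report: dict = {
        "parameters": {
            "alpha": alpha,
            "n_shuffles": n_shuffles,
            "seed": seed,
            "connectivity_mode": connectivity_mode,
            "weight_min": weight_min,
        },
        "dataset": d.counts(),
        "dico": {
            "n_labeled": len(dico.labels),
            "tallies": dico.tallies(d),
            "tallies_url_only": dico.tallies(d, url_only=True),
            "minor": sorted(dico.minor_labels, key=str),
            "fdr_threshold": dico.projection.threshold if dico.projection else None,
        },
        "nec": {
            "n_validated": len(nec.nec),
            "sizes": nec.sizes(),
            "fdr_threshold": nec.projection.threshold if nec.projection else None,
            "urls_per_validated_account": _urls_per_account(d, nec.validated_users),
            "urls_per_nonvalidated_account": _urls_per_account(
                d, _url_sharing_users(d) - nec.validated_users
            ),
        },
        "echo_chambers": {
            "n_chambers": len(chambers),
            "n_members": sum(len(c.members) for c in chambers),
            "n_excluded": len(excluded),
            "chambers": [c.to_dict() for c in chambers],
            "members_pct_of_users": round(
                100.0 * sum(len(c.members) for c in chambers) / d.n_users, 2
            ) if d.n_users else None,
        },
        "flow": {
            "nodes": sorted((str(n) for n in flow.nodes), key=str) if flow is not None else [],
            "edges": sorted(
                [[str(a), str(b), int(dd["weight"])] for a, b, dd in flow.edges(data=True)]
            ) if flow is not None else [],
        },
    }

    if trust_labels is not None:
        member_group = {u: f"chamber_{c.id}" for c in chambers for u in c.members}
        groups_all = {u: "all" for u in d.users}
        in_chambers = set(member_group)
        in_out = {u: ("in_chamber" if u in in_chambers else "outside") for u in d.users}
        report["trust"] = {
            "overall": [t.to_dict() for t in tally_trust(d, groups_all, trust_labels, url_map)],
            "per_chamber": [t.to_dict() for t in tally_trust(d, member_group, trust_labels, url_map)],
            "chamber_vs_outside": [t.to_dict() for t in tally_trust(d, in_out, trust_labels, url_map)],
        }
    else:
        report["trust"] = "skipped"

    if out_dir is not None:
        objects: dict = {"report": report}
        objects["retweet_network"] = rt.graph
        if dico.projection is not None:
            objects["dico_projection"] = dico.projection.graph
        if nec.projection is not None:
            objects["nec_projection"] = nec.projection.graph
        if flow is not None:
            objects["flow"] = flow
        write_outputs(objects, out_dir)
    return report


def _url_sharing_users(d: Dataset) -> set[str]:
    return {p.author_id for p in d.posts if p.urls}


def _urls_per_account(d: Dataset, users: set[str]) -> float | None:
    """Mean number of URL-bearing posts per account over ``users``."""
    if not users:
        return None
    n_posts = sum(1 for p in d.posts if p.urls and p.author_id in users)
    return n_posts / len(users)


def urls_per_account(n_urls: int, n_users: int, ndigits: int | None = None) -> float:
    """URL-bearing posts per account from aggregate row counts."""
    if n_users <= 0:
        raise ValueError("n_users must be positive")
    v = n_urls / n_users
    return round(v, ndigits) if ndigits is not None else v


def validated_share_pct(n_validated: int, n_nonvalidated: int, ndigits: int = 2) -> float:
    """Percentage of URL-sharing users that were validated into NECs."""
    total = n_validated + n_nonvalidated
    if total <= 0:
        raise ValueError("need a positive user total")
    return round(100.0 * n_validated / total, ndigits)


def remaining_after_exclusions(total: int, *excluded: int) -> int:
    """Users left after successive exclusion filters (never negative-checked
    away: a negative remainder is a hard error)."""
    out = total - sum(excluded)
    if out < 0:
        raise ValueError(f"exclusions {excluded} exceed total {total}")
    return out


def share_of_total_pct(part: int, total: int, ndigits: int = 2) -> float:
    """``part`` as a percentage of ``total``."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * part / total, ndigits)
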