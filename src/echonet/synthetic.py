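"""Seeded synthetic post datasets with planted structure.

The generator plants, per block, a set of verified content creators and an
unverified audience that retweets its own block's verified users at a high
rate ``p_in`` and other blocks' at ``p_out`` (blocks = recoverable discursive
communities).  Inside the first block(s) it plants news-engagement groups:
users that heavily share a common pool of URLs, wired together with a random
spanning tree of mutual retweets (plus extra pairs) so the planted group is
weakly connected and satisfies the echo-chamber definition by construction.
Everything is drawn from one ``numpy`` generator seeded with the master
seed, so the same config always yields a byte-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from echonet.io import Dataset, PostRecord

_DEFAULT_TRUST_MIX = {"T": 0.4, "N": 0.4, "UNC": 0.2}


@dataclass
class SyntheticConfig:
    n_blocks: int = 2
    n_verified_per_block: int = 5
    n_unverified_per_block: int = 60
    p_in: float = 0.6
    p_out: float = 0.01
    #: planted news-engagement group (one, inside block 0); 0 disables
    nec_size: int = 8
    nec_pool_size: int = 20
    nec_share_rate: float = 0.9
    #: within-group retweet probability per ordered pair (on top of the
    #: spanning tree that guarantees connectivity)
    nec_retweet_rate: float = 0.3
    #: background URL sharing: every unverified user shares this many URLs
    #: drawn from a common background pool
    background_shares: int = 3
    background_pool_size: int = 300
    trust_mix: dict = field(default_factory=lambda: dict(_DEFAULT_TRUST_MIX))
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_in", "p_out", "nec_share_rate", "nec_retweet_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_blocks < 1 or self.n_verified_per_block < 1 or self.n_unverified_per_block < 1:
            raise ValueError("block structure requires at least 1 block and 1 user per layer")
        if self.nec_size > self.n_unverified_per_block:
            raise ValueError(
                f"planted NEC of {self.nec_size} users does not fit in a block of "
                f"{self.n_unverified_per_block} unverified users"
            )
        if self.nec_size == 1:
            raise ValueError("a planted NEC needs at least 2 users (or 0 to disable)")
        if abs(sum(self.trust_mix.values()) - 1.0) > 1e-9:
            raise ValueError("trust_mix weights must sum to 1")
        if set(self.trust_mix) - {"T", "N", "UNC"}:
            raise ValueError("trust_mix keys must be within {T, N, UNC}")


@dataclass
class GroundTruth:
    """Planted structure: block (discursive) labels, NEC members, chamber."""

    dico: dict[str, int]
    nec_members: frozenset[str]
    chamber_members: frozenset[str]
    url_labels: dict[str, str]

    def trust_label_rows(self) -> list[tuple[str, str]]:
        return sorted(self.url_labels.items())


def generate_dataset(cfg: SyntheticConfig) -> tuple[Dataset, GroundTruth]:
    """Generate a post dataset with planted DiCos, one planted NEC, and a
    planted echo chamber; reproducible byte-for-byte from ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    verified = [[f"v{b}_{i}" for i in range(cfg.n_verified_per_block)] for b in range(cfg.n_blocks)]
    unverified = [[f"u{b}_{j}" for j in range(cfg.n_unverified_per_block)] for b in range(cfg.n_blocks)]
    dico_truth = {u: b for b in range(cfg.n_blocks) for u in verified[b] + unverified[b]}

    posts: list[PostRecord] = []
    pid = 0

    def add(author: str, verified_flag: bool, retweeted: str | None = None, urls: tuple[str, ...] = ()) -> None:
        nonlocal pid
        posts.append(PostRecord(
            post_id=f"t{pid}",
            author_id=author,
            author_verified=verified_flag,
            retweeted_author_id=retweeted,
            urls=urls,
        ))
        pid += 1

    # every verified user posts one original tweet so its verified flag is observable
    for b in range(cfg.n_blocks):
        for v in verified[b]:
            add(v, True)

    # audience retweets: Bernoulli per (unverified, verified) pair at block rates
    for b in range(cfg.n_blocks):
        for u in unverified[b]:
            for c in range(cfg.n_blocks):
                rate = cfg.p_in if b == c else cfg.p_out
                for v in verified[c]:
                    if rng.random() < rate:
                        add(u, False, retweeted=v)

    # planted NEC inside block 0: heavy sharing of a common URL pool
    nec_members: list[str] = []
    pool: list[str] = []
    if cfg.nec_size >= 2:
        nec_members = unverified[0][: cfg.nec_size]
        pool = [f"https://necnews{k}.com/story{k}" for k in range(cfg.nec_pool_size)]
        for u in nec_members:
            shared = tuple(url for url in pool if rng.random() < cfg.nec_share_rate)
            if shared:
                add(u, False, urls=shared)
        # connectivity: random spanning tree of within-group retweets ...
        order = list(nec_members)
        rng.shuffle(order)
        for idx in range(1, len(order)):
            target = order[int(rng.integers(idx))]
            add(order[idx], False, retweeted=target)
        # ... plus extra within-group retweets for realistic clustering
        for u in nec_members:
            for w in nec_members:
                if u != w and rng.random() < cfg.nec_retweet_rate:
                    add(u, False, retweeted=w)

    # background URL sharing by every unverified user
    background = [f"https://bgnews{k}.org/item{k}" for k in range(cfg.background_pool_size)]
    if cfg.background_shares > 0 and cfg.background_pool_size > 0:
        for b in range(cfg.n_blocks):
            for u in unverified[b]:
                picks = rng.choice(cfg.background_pool_size, size=min(cfg.background_shares, cfg.background_pool_size), replace=False)
                add(u, False, urls=tuple(background[int(k)] for k in sorted(picks)))

    # trust labels per generated domain
    labels = sorted(cfg.trust_mix)
    weights = np.array([cfg.trust_mix[lab] for lab in labels])
    url_labels: dict[str, str] = {}
    for url in pool + background:
        domain = url.split("//", 1)[1].split("/", 1)[0]
        url_labels[domain] = labels[int(rng.choice(len(labels), p=weights))]

    gt = GroundTruth(
        dico=dico_truth,
        nec_members=frozenset(nec_members),
        chamber_members=frozenset(nec_members),
        url_labels=url_labels,
    )
    return Dataset(posts=posts), gt
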