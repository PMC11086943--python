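"""URL canonicalization and trust-label tallies.

Shortened links are resolved through a user-supplied short->long mapping
table (no live HTTP), then normalized: scheme/host lowercased, fragments and
tracking query parameters stripped.  The registrable domain is extracted
with an embedded subset of the public-suffix list covering common
multi-label suffixes; the canonical long URL is the identity of a shared
news item, its registrable domain the key for trust labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from urllib.parse import parse_qsl, urlencode, urlsplit, urlunsplit

from echonet.io import Dataset, TrustLabelTable

logger = logging.getLogger("echonet.misinfo")

#: Query parameters that identify the sharer, not the content.
TRACKING_PARAMS = ("fbclid", "gclid", "igshid")
TRACKING_PREFIXES = ("utm_",)

#: Multi-label public suffixes (subset of the public-suffix list; single-label
#: TLDs need no entry — the fallback takes the last label as the suffix).
_PUBLIC_SUFFIXES = frozenset({
    "co.uk", "org.uk", "ac.uk", "gov.uk", "net.uk", "me.uk", "ltd.uk", "plc.uk",
    "co.jp", "ne.jp", "or.jp", "ac.jp", "go.jp",
    "com.au", "net.au", "org.au", "edu.au", "gov.au", "id.au",
    "co.nz", "net.nz", "org.nz", "govt.nz", "ac.nz",
    "com.br", "net.br", "org.br", "gov.br",
    "com.mx", "org.mx", "gob.mx",
    "com.ar", "org.ar", "gob.ar", "net.ar",
    "co.in", "net.in", "org.in", "gov.in", "ac.in",
    "co.za", "org.za", "web.za", "gov.za",
    "com.tr", "org.tr", "gov.tr", "edu.tr",
    "com.cn", "net.cn", "org.cn", "gov.cn",
    "com.hk", "org.hk", "edu.hk",
    "com.sg", "org.sg", "edu.sg",
    "co.kr", "or.kr", "go.kr", "ac.kr",
    "com.tw", "org.tw",
    "co.il", "org.il", "gov.il", "ac.il",
    "com.ua", "gov.ua",
    "com.ru", "org.ru",
    "gov.it", "edu.it",
    "co.it",  # regional-style second levels are rare in .it; registrable = label.it otherwise
})


def registrable_domain(host: str) -> str:
    """Registrable domain of a host: public suffix plus one label.

    ``news.site.co.uk -> site.co.uk``; ``a.b.example.com -> example.com``;
    bare suffixes and IPs/localhost are returned unchanged.
    """
    host = host.strip(".").lower()
    labels = host.split(".")
    if len(labels) <= 2:
        return host
    if host.replace(".", "").isdigit():  # IPv4 literal
        return host
    for take in (3, 2):  # longest matching multi-label suffix wins
        if len(labels) > take and ".".join(labels[-take:]) in _PUBLIC_SUFFIXES:
            return ".".join(labels[-(take + 1):])
    return ".".join(labels[-2:])


def canonicalize_url(url: str, url_map: dict[str, str] | None = None) -> tuple[str, str] | None:
    """Canonicalize one URL; returns (canonical_url, registrable_domain) or
    None for unparseable input (callers count drops).

    Steps: map short->long if a mapping entry exists; lowercase scheme and
    host; drop the fragment and tracking query parameters (``utm_*`` and
    click identifiers); scheme-less inputs are parsed as ``http://``.
    """
    if not isinstance(url, str) or not url.strip():
        return None
    url = url.strip()
    if url_map and url in url_map:
        url = url_map[url]
    if "://" not in url:
        url = "http://" + url
    try:
        parts = urlsplit(url)
    except ValueError:
        return None
    host = (parts.hostname or "").lower()
    if not host or "." not in host and host != "localhost":
        return None
    netloc = host
    if parts.port is not None:
        netloc = f"{host}:{parts.port}"
    query = [
        (k, v)
        for k, v in parse_qsl(parts.query, keep_blank_values=True)
        if k.lower() not in TRACKING_PARAMS and not k.lower().startswith(TRACKING_PREFIXES)
    ]
    canonical = urlunsplit((parts.scheme.lower(), netloc, parts.path, urlencode(query), ""))
    return canonical, registrable_domain(host)


@dataclass
class TrustTally:
    """Per-group trust-label counts over shared URLs.

    ``counts`` weights each share (multiplicity); ``distinct_counts`` counts
    each canonical URL once per group.  ``probabilities`` are share-weighted
    P(label | group), None when the group shared nothing.
    """

    group: object
    counts: dict[str, int] = field(default_factory=lambda: {"T": 0, "N": 0, "UNC": 0})
    distinct_counts: dict[str, int] = field(default_factory=lambda: {"T": 0, "N": 0, "UNC": 0})
    dropped_urls: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def probabilities(self) -> dict[str, float] | None:
        t = self.total
        if t == 0:
            return None
        return {lab: c / t for lab, c in self.counts.items()}

    @property
    def nt_ratio(self) -> float | None:
        """N/T share ratio; None when no trustworthy shares exist."""
        if self.counts["T"] == 0:
            return None
        return self.counts["N"] / self.counts["T"]

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "counts": dict(self.counts),
            "distinct_counts": dict(self.distinct_counts),
            "total": self.total,
            "probabilities": self.probabilities,
            "nt_ratio": self.nt_ratio,
            "dropped_urls": self.dropped_urls,
        }


def tally_trust(
    d: Dataset,
    groups: dict[str, object],
    labels: TrustLabelTable,
    url_map: dict[str, str] | None = None,
) -> list[TrustTally]:
    """Tally T/N/UNC URL shares per user group.

    Every distinct canonical URL in a grouped user's post contributes one
    share to the label of its registrable domain in that user's group; the
    distinct count ignores multiplicity within the group.  Label lookup is by
    registrable domain only.
    """
    tallies: dict[object, TrustTally] = {}
    seen: dict[object, set[str]] = {}
    for post in d.posts:
        gid = groups.get(post.author_id)
        if gid is None:
            continue
        tally = tallies.setdefault(gid, TrustTally(group=gid))
        group_seen = seen.setdefault(gid, set())
        for raw in dict.fromkeys(post.urls):  # distinct URLs within one post
            canon = canonicalize_url(raw, url_map)
            if canon is None:
                tally.dropped_urls += 1
                continue
            cu, domain = canon
            lab = labels.get(domain)
            tally.counts[lab] += 1
            if cu not in group_seen:
                group_seen.add(cu)
                tally.distinct_counts[lab] += 1
    out = sorted(tallies.values(), key=lambda t: str(t.group))
    logger.info("tally_trust: %d groups, %d total shares", len(out), sum(t.total for t in out))
    return out
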