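"""Canonical data records and file I/O.

Post tables are consumed as JSONL (one object per line) or CSV with columns
``post_id,author_id,author_verified,retweeted_author_id,urls,timestamp``;
in CSV the URL list is joined with ``|``.  Trust labels are a two-column CSV
``domain,label`` with labels in ``{T, N, UNC}``.

Malformed rows are skipped and counted, never silently ignored; loading a
file where more than half the rows are malformed is treated as a format
error.  Self-retweets (``retweeted_author_id == author_id``) are dropped at
load with a logged count: a retweet is read as endorsement of *someone
else's* content.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import networkx as nx

logger = logging.getLogger("echonet.io")

VALID_TRUST_LABELS = ("T", "N", "UNC")

_CSV_COLUMNS = ["post_id", "author_id", "author_verified", "retweeted_author_id", "urls", "timestamp"]
_URL_SEP = "|"


class FormatError(ValueError):
    """Raised when an input file is structurally unusable."""


@dataclass(frozen=True)
class PostRecord:
    """A single tweet or retweet.

    ``retweeted_author_id`` is ``None`` for original posts.  ``urls`` holds
    the raw URL strings as shared; canonicalization happens downstream.
    """

    post_id: str
    author_id: str
    author_verified: bool = False
    retweeted_author_id: str | None = None
    urls: tuple[str, ...] = ()
    timestamp: str | None = None

    @property
    def is_retweet(self) -> bool:
        return self.retweeted_author_id is not None

    def to_dict(self) -> dict[str, Any]:
        return {
            "post_id": self.post_id,
            "author_id": self.author_id,
            "author_verified": self.author_verified,
            "retweeted_author_id": self.retweeted_author_id,
            "urls": list(self.urls),
            "timestamp": self.timestamp,
        }


@dataclass
class Dataset:
    """A loaded post table plus the drop counters accumulated at load."""

    posts: list[PostRecord]
    dropped_malformed: int = 0
    dropped_self_retweets: int = 0
    dropped_duplicate_ids: int = 0

    @property
    def n_posts(self) -> int:
        return len(self.posts)

    @property
    def n_retweets(self) -> int:
        return sum(1 for p in self.posts if p.is_retweet)

    @property
    def n_url_posts(self) -> int:
        return sum(1 for p in self.posts if p.urls)

    @property
    def users(self) -> set[str]:
        out: set[str] = set()
        for p in self.posts:
            out.add(p.author_id)
            if p.retweeted_author_id is not None:
                out.add(p.retweeted_author_id)
        return out

    @property
    def n_users(self) -> int:
        return len(self.users)

    @property
    def n_verified_users(self) -> int:
        return sum(1 for v in self.verified_map().values() if v)

    def verified_map(self) -> dict[str, bool]:
        """Verified status per user id.

        A user is verified iff some post they authored carries the verified
        flag.  Users that only ever appear as retweeted authors have no flag
        of their own and default to unverified.
        """
        out: dict[str, bool] = {}
        for p in self.posts:
            out[p.author_id] = out.get(p.author_id, False) or p.author_verified
            if p.retweeted_author_id is not None:
                out.setdefault(p.retweeted_author_id, False)
        return out

    def counts(self) -> dict[str, int]:
        return {
            "users": self.n_users,
            "verified_users": self.n_verified_users,
            "posts": self.n_posts,
            "retweets": self.n_retweets,
            "url_posts": self.n_url_posts,
            "dropped_malformed": self.dropped_malformed,
            "dropped_self_retweets": self.dropped_self_retweets,
            "dropped_duplicate_ids": self.dropped_duplicate_ids,
        }


@dataclass
class TrustLabelTable:
    """Registrable-domain -> trust label map; unknown domains are UNC."""

    labels: dict[str, str] = field(default_factory=dict)

    def get(self, domain: str) -> str:
        return self.labels.get(domain.lower(), "UNC")

    def __len__(self) -> int:
        return len(self.labels)


def _coerce_record(raw: Mapping[str, Any]) -> PostRecord | None:
    """Build a PostRecord from a raw mapping; None if it cannot be salvaged."""
    post_id = raw.get("post_id")
    author_id = raw.get("author_id")
    if post_id in (None, "") or author_id in (None, ""):
        return None
    verified = raw.get("author_verified", False)
    if isinstance(verified, str):
        verified = verified.strip().lower() in ("true", "1", "yes", "t")
    rt = raw.get("retweeted_author_id")
    if rt in ("", None):
        rt = None
    urls = raw.get("urls", [])
    if isinstance(urls, str):
        urls = [u for u in urls.split(_URL_SEP) if u] if urls else []
    elif urls is None:
        urls = []
    ts = raw.get("timestamp")
    if ts in ("", None):
        ts = None
    return PostRecord(
        post_id=str(post_id),
        author_id=str(author_id),
        author_verified=bool(verified),
        retweeted_author_id=str(rt) if rt is not None else None,
        urls=tuple(str(u) for u in urls),
        timestamp=str(ts) if ts is not None else None,
    )


def _iter_raw_rows(path: Path, fmt: str) -> Iterable[Mapping[str, Any] | None]:
    if fmt == "jsonl":
        with path.open() as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError:
                    yield None
                    continue
                yield obj if isinstance(obj, dict) else None
    elif fmt == "csv":
        with path.open(newline="") as fh:
            for row in csv.DictReader(fh):
                yield row
    else:
        raise ValueError(f"unknown posts format: {fmt!r} (expected 'jsonl' or 'csv')")


def read_posts(path: str | Path, format: str | None = None) -> Dataset:
    """Load a post table, skipping and counting malformed rows.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"jsonl"`` or ``"csv"``; inferred from the suffix when omitted.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    FormatError
        If more than 50% of non-empty rows are malformed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"

    posts: list[PostRecord] = []
    seen_ids: set[str] = set()
    n_rows = n_malformed = n_self = n_dupe = 0
    for raw in _iter_raw_rows(path, format):
        n_rows += 1
        rec = _coerce_record(raw) if raw is not None else None
        if rec is None:
            n_malformed += 1
            continue
        if rec.retweeted_author_id == rec.author_id:
            n_self += 1
            continue
        if rec.post_id in seen_ids:
            n_dupe += 1
            continue
        seen_ids.add(rec.post_id)
        posts.append(rec)

    if n_rows == 0:
        logger.warning("read_posts(%s): empty file", path)
    if n_rows and n_malformed > n_rows / 2:
        raise FormatError(f"{path}: {n_malformed}/{n_rows} rows malformed; refusing to load")
    if n_malformed:
        logger.warning("read_posts(%s): skipped %d malformed rows", path, n_malformed)
    if n_self:
        logger.info("read_posts(%s): dropped %d self-retweets", path, n_self)
    if n_dupe:
        logger.warning("read_posts(%s): dropped %d duplicate post_ids", path, n_dupe)
    return Dataset(
        posts=posts,
        dropped_malformed=n_malformed,
        dropped_self_retweets=n_self,
        dropped_duplicate_ids=n_dupe,
    )


def write_posts(dataset: Dataset, path: str | Path, format: str | None = None) -> None:
    """Serialize a Dataset back to JSONL or CSV (round-trip safe)."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        with path.open("w") as fh:
            for p in dataset.posts:
                fh.write(json.dumps(p.to_dict(), sort_keys=True) + "\n")
    elif format == "csv":
        with path.open("w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
            w.writeheader()
            for p in dataset.posts:
                d = p.to_dict()
                d["urls"] = _URL_SEP.join(d["urls"])
                d["retweeted_author_id"] = d["retweeted_author_id"] or ""
                d["timestamp"] = d["timestamp"] or ""
                w.writerow(d)
    else:
        raise ValueError(f"unknown posts format: {format!r}")


def read_trust_labels(path: str | Path) -> TrustLabelTable:
    """Load a ``domain,label`` CSV with labels in {T, N, UNC}.

    Duplicate domains keep the last occurrence (warned); a label outside the
    three codes is a fatal validation error naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels: dict[str, str] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for idx, row in enumerate(reader, start=1):
            if not row or (idx == 1 and [c.strip().lower() for c in row[:2]] == ["domain", "label"]):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{idx}: expected 'domain,label', got {row!r}")
            domain = row[0].strip().lower()
            label = row[1].strip().upper()
            if label not in VALID_TRUST_LABELS:
                raise FormatError(
                    f"{path}:{idx}: invalid trust label {row[1]!r} for {domain!r} "
                    f"(expected one of {VALID_TRUST_LABELS})"
                )
            if domain in labels:
                logger.warning("read_trust_labels(%s): duplicate domain %r, last wins", path, domain)
            labels[domain] = label
    return TrustLabelTable(labels=labels)


def read_url_map(path: str | Path) -> dict[str, str]:
    """Load a short->long URL mapping CSV (columns ``short,long``)."""
    path = Path(path)
    out: dict[str, str] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for idx, row in enumerate(reader, start=1):
            if not row or (idx == 1 and [c.strip().lower() for c in row[:2]] == ["short", "long"]):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{idx}: expected 'short,long', got {row!r}")
            out[row[0].strip()] = row[1].strip()
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_graph(g: nx.Graph, out_dir: Path, name: str) -> list[Path]:
    gml = out_dir / f"{name}.graphml"
    nx.write_graphml(g, gml)
    edges = out_dir / f"{name}.edges.csv"
    with edges.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target", "weight"])
        for u, v, data in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            w.writerow([u, v, data.get("weight", 1)])
    return [gml, edges]


def write_outputs(objects: Mapping[str, Any], out_dir: str | Path) -> dict[str, str]:
    """Write graphs (GraphML + weighted edge-list CSV) and JSON-able reports.

    Returns a manifest mapping file name to its SHA-256 content checksum;
    the manifest itself is written as ``manifest.json``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write-probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    written: list[Path] = []
    for name, obj in objects.items():
        if isinstance(obj, (nx.Graph, nx.DiGraph)):
            written.extend(_write_graph(obj, out_dir, name))
        else:
            p = out_dir / f"{name}.json"
            with p.open("w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
                fh.write("\n")
            written.append(p)

    manifest = {p.name: _sha256(p) for p in sorted(written)}
    with (out_dir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
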