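# echonet

Entropy-based detection of echo chambers in social-media post data.

The method takes a table of posts (tweets/retweets with author, verified
flag, retweeted author and shared URLs) and runs two statistically
validated detection paths against a maximum-entropy null model:

1. **Discursive communities (DiCo).** Verified and unverified users form a
   bipartite retweet network. A Bipartite Configuration Model (BiCM) —
   the maximum-entropy ensemble constrained to the observed degree
   sequences — provides per-link probabilities; co-retweeter counts of
   verified-user pairs are tested against their exact Poisson–binomial
   null distribution, filtered at FDR level α (Benjamini–Hochberg), and
   the validated projection is partitioned with best-of-N Louvain.
   Community labels are then extended to all users by a two-phase
   majority label propagation over the undirected retweet network.
2. **News-engagement communities (NEC).** The same validation machinery is
   applied to the user/URL bipartite network (after URL canonicalization
   and short-URL resolution via a mapping table), projected on the user
   layer; communities of the validated projection are NECs, ids ranked by
   size.

**Echo chambers** are groups of users that share a NEC, share a DiCo, and
form a weakly connected component of the retweet network. The package
reports their membership, average undirected clustering coefficients, an
aggregated between-chamber retweet flow network, and — given a
`domain,label` trust table with labels in `{T, N, UNC}` — per-group tallies
of trustworthy/untrustworthy URL traffic.

A seeded synthetic generator (`echonet.synthetic`) plants block-structured
retweet activity, a heavy URL-sharing group and a connected chamber, so the
whole pipeline is testable offline with known ground truth.

## CLI

```bash
# generate a synthetic fixture with planted structure
echonet synth --seed 2 --out posts.jsonl --trust-out trust.csv

# full pipeline: DiCo + NEC + echo chambers + report
echonet run --posts posts.jsonl --alpha 0.05 --shuffles 1000 --seed 1 \
    --trust-labels trust.csv --url-map urlmap.csv --out out/

# single stages with cached intermediates
echonet dico --posts posts.jsonl --out out/
echonet nec  --posts posts.jsonl --out out/
echonet echo --posts posts.jsonl --out out/   # needs dico.json + nec.json
```

`out/` receives GraphML + weighted edge-list CSVs for the retweet network,
the validated projections and the aggregated flow network, `report.json`
with all summary tables, and `manifest.json` with content checksums
(identical configs give identical checksums). All flags can be supplied via
`--config file` with `key=value` lines; explicit flags win.

Input formats:

* posts — JSONL with fields `post_id, author_id, author_verified,
  retweeted_author_id, urls, timestamp`, or CSV with the same columns and
  URLs joined by `|`;
* trust labels — CSV `domain,label`, labels in `{T, N, UNC}`;
* URL map — CSV `short,long`.

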