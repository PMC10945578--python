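"""Rank-weighted gene-set enrichment over a query's bicor coefficients,
plus overrepresentation (hypergeometric) tests on top-N gene lists.

The ranked list is the query's bicor coefficients against one target
tissue, sorted descending; positive enrichment scores mark *activated*
pathways (co-expressed with the source gene), negative scores mark
*suppressed* ones.  The null permutes gene-set membership labels over the
ranked universe of expressed genes — the standard preranked null, since a
coefficient list admits no sample permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GeneSetCollection
from .gene_query import QueryResult
from .robust_corr import bh_adjust

logger = logging.getLogger(__name__)


def ranked_from_query(result: QueryResult, tissue: str) -> pd.Series:
    """Bicor coefficients of a query restricted to one target tissue,
    sorted descending — the ranked list GSEA consumes."""
    rec = result.records
    rec = rec.loc[(rec["tissue"] == tissue) & np.isfinite(rec["bicor"])]
    if rec.empty:
        raise ValueError(f"query has no finite records in tissue {tissue!r}")
    s = pd.Series(rec["bicor"].to_numpy(), index=rec["gene"].to_numpy(), name="weight")
    return s.sort_values(ascending=False, kind="mergesort")


# ---------------------------------------------------------------------------
# Running enrichment score
# ---------------------------------------------------------------------------

def _es_from_positions(pos: np.ndarray, absw: np.ndarray, n: int) -> tuple[float, int]:
    """ES and peak rank from sorted hit positions.

    ``pos`` are 0-based ranks of the hits (ascending), ``absw`` the |weight|
    of every ranked gene.  The running sum gains ``|w_i| / sum_hits |w|``
    at a hit and loses ``1 / (n - s)`` at a miss; its extremes can only
    occur immediately after a hit (maxima) or immediately before one
    (minima), so the scan is O(s).
    """
    s = pos.size
    hit_w = absw[pos]
    total = hit_w.sum()
    if total == 0:
        # all member weights exactly zero: hits contribute nothing
        hit_cum = np.zeros(s)
    else:
        hit_cum = np.cumsum(hit_w) / total
    if n == s:
        miss_inc = 0.0  # degenerate: the set is the whole universe
    else:
        miss_inc = 1.0 / (n - s)
    k = np.arange(1, s + 1)
    after = hit_cum - (pos + 1 - k) * miss_inc  # value just after hit k
    before = np.concatenate(([0.0], hit_cum[:-1])) - (pos - (k - 1)) * miss_inc
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    hi, lo = after[i_max], before[i_min]
    if hi >= -lo:  # tie broken toward the positive deviation
        return float(hi), int(pos[i_max])
    return float(lo), int(pos[i_min])


def running_es(ranked: pd.Series, members) -> tuple[float, int]:
    """Signed maximum deviation of the weighted Kolmogorov-Smirnov
    running sum, and the 0-based rank at which it peaks.

    Raises ``ValueError`` when no member appears in the ranked list.
    A set spanning the whole universe is degenerate (no misses exist);
    the running-sum maximum is still returned, with a log notice.
    """
    if ranked.index.has_duplicates:
        raise ValueError("ranked list contains duplicate genes")
    w = ranked.to_numpy(dtype=float)
    if not np.isfinite(w).all():
        raise ValueError("ranked weights must be finite")
    if np.any(np.diff(w) > 0):
        raise ValueError("ranked list must be sorted by weight descending")
    member_set = set(members)
    pos = np.flatnonzero(ranked.index.isin(member_set))
    if pos.size == 0:
        raise ValueError("no gene-set member present in the ranked list")
    if pos.size == len(ranked):
        logger.info("gene set spans the entire ranked universe (degenerate ES)")
    return _es_from_positions(pos, np.abs(w), len(ranked))


# ---------------------------------------------------------------------------
# Preranked GSEA with a gene-label permutation null
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    size: int
    es: float
    nes: float
    p: float
    q: float
    direction: str  # activated | suppressed
    leading_edge: tuple[str, ...]


def gsea_preranked(
    ranked: pd.Series,
    collection: GeneSetCollection,
    nperm: int = 1000,
    seed: int | None = None,
    min_size: int = 10,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked gene-set enrichment across a collection.

    For each set the null redraws ``nperm`` same-size membership labels
    uniformly from the ranked universe (weights fixed).  The permutation
    p-value is sign-stratified with an add-one correction,

        p = (1 + #{same-sign perms with |ES*| >= |ES|}) / (1 + #same-sign),

    so p is never 0; NES divides ES by the mean |ES*| of same-sign perms.
    BH q-values span all evaluated sets.  Deterministic under a fixed
    seed.
    """
    if nperm < 100:
        raise ValueError(f"nperm must be >= 100, got {nperm}")
    if seed is None:
        raise ValueError("a seed is required for the permutation null")
    rng = np.random.default_rng(seed)
    n = len(ranked)
    absw = np.abs(ranked.to_numpy(dtype=float))
    rows = []
    for name in collection.names():
        members = collection.members(name)
        pos = np.flatnonzero(ranked.index.isin(set(members)))
        size = pos.size
        if size == 0:
            logger.info("set %s: no member in the ranked universe, skipped", name)
            continue
        if not (min_size <= size <= max_size):
            logger.info("set %s: size %d outside [%d, %d], skipped",
                        name, size, min_size, max_size)
            continue
        es, peak = _es_from_positions(pos, absw, n)
        perm_es = np.empty(nperm)
        for b in range(nperm):
            ppos = np.sort(rng.choice(n, size=size, replace=False))
            perm_es[b], _ = _es_from_positions(ppos, absw, n)
        if es > 0:
            same = perm_es > 0
        elif es < 0:
            same = perm_es < 0
        else:
            same = np.zeros(nperm, dtype=bool)
        n_same = int(same.sum())
        if n_same == 0:
            p, nes = 1.0, float("nan")
        else:
            exceed = int((np.abs(perm_es[same]) >= abs(es)).sum())
            p = (1 + exceed) / (n_same + 1)
            nes = es / np.mean(np.abs(perm_es[same]))
        if es >= 0:
            direction = "activated"
            leading = tuple(ranked.index[p_] for p_ in pos if p_ <= peak)
        else:
            direction = "suppressed"
            leading = tuple(ranked.index[p_] for p_ in pos if p_ >= peak)
        rows.append((name, size, es, nes, p, direction, ",".join(leading)))
    if not rows:
        logger.warning("no gene set evaluable after size filtering")
        return pd.DataFrame(
            columns=["set", "size", "es", "nes", "p", "q", "direction", "leading_edge"]
        )
    out = pd.DataFrame(
        rows, columns=["set", "size", "es", "nes", "p", "direction", "leading_edge"]
    )
    out.insert(5, "q", bh_adjust(out["p"].to_numpy()))
    return out


# ---------------------------------------------------------------------------
# Overrepresentation
# ---------------------------------------------------------------------------

def ora_test(hits, members, universe) -> tuple[float, int, float]:
    """One-sided hypergeometric overrepresentation test.

    Draws ``|hits|`` genes from the universe containing the set's members
    as successes; p = P(X >= k) for the observed overlap k.  Returns
    ``(p, overlap, fold_enrichment)``.  Invariant to the order of hits
    and members.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValueError("empty universe")
    uni_set = set(uni)
    hit_list = list(dict.fromkeys(hits))
    if not set(hit_list) <= uni_set:
        missing = sorted(set(hit_list) - uni_set)[:5]
        raise ValueError(f"hits not contained in universe, e.g. {missing}")
    mem = set(members) & uni_set
    U, K, nh = len(uni), len(mem), len(hit_list)
    k = len(set(hit_list) & mem)
    if K == 0:
        return 1.0, 0, float("nan")
    p = float(stats.hypergeom.sf(k - 1, U, K, nh))
    expected = K * nh / U
    fold = k / expected if expected > 0 else float("nan")
    return p, k, fold


def ora_collection(hits, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """ORA over every set in a collection, BH-adjusted across sets."""
    rows = []
    for name in collection.names():
        p, k, fold = ora_test(hits, collection.members(name), universe)
        rows.append((name, len(collection.members(name)), k, fold, p))
    out = pd.DataFrame(rows, columns=["set", "size", "overlap", "fold", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
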