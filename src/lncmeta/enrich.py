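"""Gene-set over-representation analysis and rank-based set enrichment.

ORA scores each set by the upper-tail hypergeometric probability of its
overlap with a query list against a background universe, BH-adjusted
across tested sets; a permutation-calibrated weighted Kolmogorov-Smirnov
running-sum statistic is provided for ranked inputs.  Gene sets travel in
the GMT format (name, description, members per tab-separated line).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .meta import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "ora",
    "gsea_running_sum",
    "read_gmt",
    "write_gmt",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against."""

    sets: dict = field(default_factory=dict)  # id -> (name, tuple of member ids)
    universe: frozenset = frozenset()

    def restrict(self) -> "GeneSetCollection":
        """Drop members outside the universe and any set left empty."""
        new = {}
        for sid, (name, members) in self.sets.items():
            kept = tuple(m for m in members if m in self.universe)
            if kept:
                new[sid] = (name, kept)
        return GeneSetCollection(sets=new, universe=self.universe)


def ora(
    query,
    collection: GeneSetCollection,
    min_set: int = 10,
    max_set: int = 500,
    adj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each gene set.

    p_raw = P(X >= x) for overlap x, set size K, query size n, universe
    size N; BH adjustment across the tested sets; rows sorted by adjusted
    p.  Query genes outside the universe are dropped with a log message.
    """
    universe = collection.universe
    query = set(query)
    outside = query - universe
    if outside:
        logger.warning("%d query genes outside the universe dropped", len(outside))
        query &= universe
    if not query:
        raise InputError("empty query after restriction to the universe")
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for sid, (name, members) in collection.sets.items():
        mem = set(members) & universe
        k_size = len(mem)
        if not (min_set <= k_size <= max_set):
            continue
        x = len(mem & query)
        p_raw = float(stats.hypergeom.sf(x - 1, n_universe, k_size, n_query))
        rows.append(
            {
                "set_id": sid,
                "name": name,
                "overlap": x,
                "set_size": k_size,
                "query_size": n_query,
                "universe_size": n_universe,
                "p_raw": min(p_raw, 1.0),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "set_id", "name", "overlap", "set_size", "query_size",
                "universe_size", "p_raw", "p_adj", "enriched",
            ]
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_fdr(out["p_raw"].to_numpy())
    out["enriched"] = out["p_adj"] < adj_threshold
    return out.sort_values(["p_adj", "p_raw", "set_id"]).reset_index(drop=True)


def gsea_running_sum(
    ranked_genes: pd.Series, gene_set, n_perm: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Weighted KS running-sum enrichment score with a permutation p-value.

    ``ranked_genes`` maps gene id -> score (any order; sorted internally,
    descending).  Hits advance the running sum by |score| (normalized),
    misses retreat uniformly; ES is the signed maximum deviation.  The
    p-value comes from ``n_perm`` label permutations, one-sided among
    permutations matching the observed ES sign (doubled, capped at 1).
    """
    scores = ranked_genes.sort_values(ascending=False)
    if not np.isfinite(scores.to_numpy()).all():
        raise InputError("ranking scores must be finite")
    in_set = scores.index.isin(set(gene_set))
    if not in_set.any():
        return np.nan, np.nan

    def _es(hits: np.ndarray) -> float:
        w = np.abs(scores.to_numpy())
        w_hit = np.where(hits, w, 0.0)
        total = w_hit.sum()
        if total == 0:  # all-zero scores: unweighted steps
            w_hit = hits.astype(float)
            total = w_hit.sum()
        n_miss = (~hits).sum()
        step_miss = 1.0 / n_miss if n_miss else 0.0
        run = np.cumsum(w_hit / total - np.where(hits, 0.0, step_miss))
        return float(run[np.argmax(np.abs(run))])

    es = _es(in_set)
    rng = np.random.default_rng(seed)
    null = np.array([_es(rng.permutation(in_set)) for _ in range(n_perm)])
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + n_perm)
    return es, float(min(2.0 * p, 1.0))


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Parse a GMT file; duplicate members within a set are dropped with a log."""
    sets = {}
    members_all = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: GMT line needs >=3 fields")
            sid, name, members = parts[0], parts[1], parts[2:]
            dedup = list(dict.fromkeys(m for m in members if m))
            if len(dedup) < len([m for m in members if m]):
                logger.warning("%s:%d: duplicate members in %s deduplicated", path, lineno, sid)
            sets[sid] = (name, tuple(dedup))
            members_all.update(dedup)
    uni = frozenset(universe) if universe is not None else frozenset(members_all)
    return GeneSetCollection(sets=sets, universe=uni)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for sid, (name, members) in collection.sets.items():
            fh.write("\t".join([sid, name, *members]) + "\n")
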