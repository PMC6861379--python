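"""Tissue-specificity scoring by Jensen-Shannon divergence.

A gene's expression row over tissues is converted to a density and scored
against the extreme pattern in which the gene is expressed in a single
tissue: score_t = 1 - sqrt(JSD(density, e_t)).  With base-2 entropy the
square-root JS divergence is a metric bounded by 1, so scores live in
[0, 1], reaching 1 only for genes expressed in exactly one tissue.
Gene-by-tissue expression patterns can also be hierarchically clustered
under the Manhattan (L1) distance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = ["js_distance", "specificity_scores", "cluster_genes"]


def _entropy2(p: np.ndarray) -> float:
    """Shannon entropy in bits with the 0*log0 = 0 convention."""
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def js_distance(p, q) -> float:
    """Square root of the Jensen-Shannon divergence (base-2), in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise InputError(f"length mismatch: {p.shape} vs {q.shape}")
    if (p < 0).any() or (q < 0).any():
        raise InputError("negative entries in a probability vector")
    if abs(p.sum() - 1.0) > 1e-9 or abs(q.sum() - 1.0) > 1e-9:
        raise InputError("probability vectors must sum to 1")
    m = 0.5 * (p + q)
    jsd = _entropy2(m) - 0.5 * (_entropy2(p) + _entropy2(q))
    return float(np.sqrt(max(jsd, 0.0)))


def specificity_scores(atlas: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-tissue specificity scores from a genes x tissues atlas.

    Each row is normalized to a density; score_t = 1 - js_distance(density,
    unit vector at tissue t).  Returns one row per scorable gene with a
    column per tissue plus ``max_score`` and ``max_tissue``; all-zero rows
    are excluded and logged.
    """
    if atlas.shape[1] < 2:
        raise InputError("atlas needs at least two tissues")
    x = atlas.to_numpy(dtype=float)
    if (x < 0).any():
        raise InputError("negative expression in atlas")
    rowsum = x.sum(axis=1)
    scorable = rowsum > 0
    if (~scorable).any():
        logger.warning("%d all-zero genes excluded from specificity scoring", (~scorable).sum())
    dens = x[scorable] / rowsum[scorable, None]
    n_t = dens.shape[1]

    # score_t in closed form: with e_t the unit vector, m = (p + e_t)/2 and
    # JSD = H(m) - H(p)/2, since H(e_t) = 0.
    h_p = -np.where(dens > 0, dens * np.log2(np.where(dens > 0, dens, 1.0)), 0.0).sum(axis=1)
    scores = np.empty_like(dens)
    for t in range(n_t):
        m = dens / 2.0
        m[:, t] += 0.5
        h_m = -np.where(m > 0, m * np.log2(np.where(m > 0, m, 1.0)), 0.0).sum(axis=1)
        jsd = np.maximum(h_m - 0.5 * h_p, 0.0)
        scores[:, t] = 1.0 - np.sqrt(jsd)
    out = pd.DataFrame(scores, index=atlas.index[scorable], columns=atlas.columns)
    best = np.argmax(scores, axis=1)
    out["max_score"] = scores[np.arange(scores.shape[0]), best]
    out["max_tissue"] = atlas.columns.to_numpy()[best]
    out.index.name = "gene_id"
    return out


def cluster_genes(
    atlas: pd.DataFrame, linkage: str = "complete"
) -> tuple[np.ndarray, list[str]]:
    """Hierarchical clustering of genes under the Manhattan distance.

    Returns the scipy linkage matrix and the dendrogram leaf order (gene
    ids).  Ties break deterministically on the lowest original index.
    """
    if atlas.shape[0] < 2:
        raise InputError("clustering needs at least two genes")
    d = pdist(atlas.to_numpy(dtype=float), metric="cityblock")
    z = hierarchy.linkage(d, method=linkage)
    order = hierarchy.leaves_list(z)
    return z, [str(atlas.index[i]) for i in order]
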