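"""Weighted co-expression network analysis (WGCNA-style).

Builds an unsigned weighted network a_ij = |cor(x_i, x_j)|^beta with beta
chosen for approximate scale-free topology, converts it to a topological
overlap matrix (TOM), detects modules by average-linkage clustering of the
TOM dissimilarity with eigengene-based merging, and scores each module's
association with sample traits through its eigengene (module membership
kME, gene significance GS, module-trait correlations, and the kME-GS
correlation within each module).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "ModuleSet",
    "remove_outlier_samples",
    "pick_soft_threshold",
    "adjacency_matrix",
    "tom_matrix",
    "detect_modules",
    "module_significance",
]


@dataclass
class NetworkConfig:
    beta_candidates: tuple = tuple(range(1, 21))
    rsq_target: float = 0.8
    min_module_size: int = 30
    merge_cut: float = 0.25  # eigengene dissimilarity (1 - cor) below which modules merge
    outlier_min_cluster: int = 5
    outlier_cut_height: float | None = None
    cut_height_frac: float = 0.99  # static cut at this fraction of the max merge height
    n_bins: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.rsq_target <= 1):
            raise InputError("rsq_target must lie in (0, 1]")
        if self.min_module_size <= 0 or self.outlier_min_cluster <= 0:
            raise InputError("sizes must be positive")


@dataclass
class ModuleSet:
    """Module labels with eigengenes and significance statistics.

    Label 0 is the unassigned (grey) pool.  ``eigengenes`` is modules x
    samples with unit-variance rows; ``kME`` genes x modules; ``GS`` genes
    x traits (absolute correlations); ``module_trait_r``/``_p`` modules x
    traits; ``mm_gs`` one row per module with the kME-GS correlation for
    the primary trait plus the module's average GS.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)
    kME: pd.DataFrame = field(default_factory=pd.DataFrame)
    GS: pd.DataFrame = field(default_factory=pd.DataFrame)
    module_trait_r: pd.DataFrame = field(default_factory=pd.DataFrame)
    module_trait_p: pd.DataFrame = field(default_factory=pd.DataFrame)
    mm_gs: pd.DataFrame = field(default_factory=pd.DataFrame)


def remove_outlier_samples(
    expression: pd.DataFrame, config: NetworkConfig
) -> tuple[pd.DataFrame, list[str]]:
    """Drop samples falling in small clusters of the sample dendrogram.

    Samples (columns) are clustered with Euclidean distance and average
    linkage; the tree is cut at ``outlier_cut_height`` and clusters with
    fewer than ``outlier_min_cluster`` members are removed.
    """
    if expression.shape[1] < 3:
        raise InputError("outlier screening needs >=3 samples")
    if config.outlier_cut_height is None:
        return expression, []
    x = expression.to_numpy(dtype=float).T
    z = hierarchy.linkage(x, method="average", metric="euclidean")
    labels = hierarchy.fcluster(z, t=config.outlier_cut_height, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    small = set(sizes.index[sizes < config.outlier_min_cluster])
    removed = [
        str(expression.columns[i]) for i in range(len(labels)) if labels[i] in small
    ]
    if len(removed) == expression.shape[1]:
        raise InputError("outlier cut removed every sample")
    if removed:
        logger.info("removed %d outlier samples: %s", len(removed), removed)
    return expression.drop(columns=removed), removed


def _cor_genes(expression: pd.DataFrame) -> np.ndarray:
    """Gene-gene Pearson correlation (expression is genes x samples)."""
    x = expression.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    sd = np.sqrt((x**2).sum(axis=1))
    sd[sd == 0] = np.nan
    c = (x @ x.T) / np.outer(sd, sd)
    c = np.nan_to_num(np.clip(c, -1.0, 1.0))
    np.fill_diagonal(c, 1.0)
    return c


def adjacency_matrix(expression: pd.DataFrame, beta: float) -> np.ndarray:
    """Unsigned adjacency |Pearson correlation|^beta."""
    return np.abs(_cor_genes(expression)) ** beta


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """Signed scale-free R2 and slope of log10 p(k) vs log10 mean(k) in bins."""
    if np.ptp(k) == 0:
        raise InputError("degenerate connectivity: all k equal")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        mk = k[mask].mean()
        freq = mask.mean()
        if mk > 0 and freq > 0:
            xs.append(np.log10(mk))
            ys.append(np.log10(freq))
    if len(xs) < 3:
        raise InputError("too few non-empty bins for a scale-free fit")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(r**2 * np.sign(-slope)), float(slope)


def pick_soft_threshold(
    expression: pd.DataFrame, config: NetworkConfig | None = None
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power for approximate scale-free topology.

    For each candidate beta the signed fit index R2 of the connectivity
    distribution is computed; the smallest beta reaching ``rsq_target``
    wins, falling back (with a warning) to the best-fitting beta if none
    does.  Returns (beta, fit table with signed R2, slope and mean k).
    """
    config = config or NetworkConfig()
    if expression.shape[0] < 10 or expression.shape[1] < 4:
        raise InputError("need >=10 genes and >=4 samples")
    cor = np.abs(_cor_genes(expression))
    rows = []
    for beta in config.beta_candidates:
        a = cor**beta
        k = a.sum(axis=0) - 1.0  # exclude the unit diagonal
        try:
            rsq, slope = _scale_free_fit(k, config.n_bins)
        except InputError as exc:
            logger.warning("beta=%s skipped: %s", beta, exc)
            continue
        rows.append({"beta": beta, "signed_R2": rsq, "slope": slope, "mean_k": k.mean()})
    fit = pd.DataFrame(rows)
    if fit.empty:
        raise InputError("no usable soft-threshold candidate")
    ok = fit[fit["signed_R2"] >= config.rsq_target]
    if len(ok):
        beta = int(ok.iloc[0]["beta"])
    else:
        beta = int(fit.loc[fit["signed_R2"].idxmax(), "beta"])
        warnings.warn(
            f"no candidate reached signed R2 >= {config.rsq_target}; using beta={beta}",
            stacklevel=2,
        )
    return beta, fit


def tom_matrix(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a weighted network.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_{u != i,j} a_iu a_uj and k the connectivity excluding the
    diagonal; TOM_ii = 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InputError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise InputError("adjacency must be symmetric")
    if (a < -1e-12).any() or (a > 1 + 1e-12).any():
        raise InputError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(a), 1.0):
        raise InputError("adjacency must have a unit diagonal")
    # (A @ A)_ij counts u = i and u = j, each contributing a_ij when diag = 1
    l_mat = a @ a - 2.0 * a
    k = a.sum(axis=0) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l_mat + a) / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    tom: np.ndarray,
    config: NetworkConfig | None = None,
    expression: pd.DataFrame | None = None,
) -> pd.Series:
    """Module labels from average-linkage clustering of the TOM dissimilarity.

    The tree on 1 - TOM is cut at a static height: the midpoint of the
    largest gap between consecutive merge heights in the dendrogram's top
    quarter (which separates the final between-module joins even when TOM
    dissimilarities compress toward 1 at high beta), falling back to
    ``cut_height_frac`` of the maximum merge height when no gap stands
    out.  Branches smaller than ``min_module_size`` go to label 0.  If
    ``expression`` is given, modules whose eigengenes have dissimilarity
    1 - cor below ``merge_cut`` are merged iteratively.  Labels are
    renumbered 1, 2, ... by decreasing module size.
    """
    config = config or NetworkConfig()
    n = tom.shape[0]
    index = expression.index if expression is not None else pd.RangeIndex(n)
    if config.min_module_size > n:
        return pd.Series(np.zeros(n, dtype=int), index=index, name="module")
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    cut = _static_cut_height(z[:, 2], config.cut_height_frac)
    raw = hierarchy.fcluster(z, t=cut, criterion="distance")
    labels = np.asarray(raw, dtype=int)
    sizes = pd.Series(labels).value_counts()
    for lab, sz in sizes.items():
        if sz < config.min_module_size:
            labels[labels == lab] = 0
    if (labels == 0).all():
        logger.warning("no module reached min_module_size=%d", config.min_module_size)
        return pd.Series(labels, index=index, name="module")

    if expression is not None:
        labels = _merge_close_modules(expression, labels, config.merge_cut)

    # renumber by decreasing size (ties on the smaller old label), 0 stays unassigned
    counts = pd.Series(labels[labels != 0]).value_counts()
    order = sorted(counts.index, key=lambda l: (-counts[l], l))
    remap = {old: i + 1 for i, old in enumerate(order)}
    labels = np.array([remap.get(l, 0) for l in labels], dtype=int)
    return pd.Series(labels, index=index, name="module")


def _static_cut_height(heights: np.ndarray, frac: float) -> float:
    """Cut below the final between-module joins of the dendrogram.

    Looks for the largest gap between consecutive merge heights in the top
    quarter of merges; a gap clearly dominating the local spacing marks the
    boundary between within-module and between-module joins and the cut
    goes to its midpoint.  Otherwise the cut is ``frac`` of the maximum.
    """
    h = np.sort(heights)
    if h[-1] <= 0:
        return 0.0
    tail = h[-max(3, h.size // 4):]
    gaps = np.diff(tail)
    gi = int(np.argmax(gaps))
    others = np.delete(gaps, gi)
    if gaps[gi] > 0 and (others.size == 0 or gaps[gi] > 3.0 * np.median(others)):
        return float((tail[gi] + tail[gi + 1]) / 2.0)
    return float(frac * h[-1])


def _eigengene(x: np.ndarray) -> np.ndarray:
    """Unit-variance first principal component of a samples x genes block."""
    xs = x - x.mean(axis=0)
    sd = xs.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    xs = xs / sd
    u, s, _ = np.linalg.svd(xs, full_matrices=False)
    e = u[:, 0]
    cors = (xs * e[:, None]).mean(axis=0)
    if cors.mean() < 0:
        e = -e
    sd_e = e.std(ddof=1)
    return e / sd_e if sd_e > 0 else e


def _merge_close_modules(
    expression: pd.DataFrame, labels: np.ndarray, merge_cut: float
) -> np.ndarray:
    """Iteratively merge the closest eigengene pair while 1 - cor < cut."""
    labels = labels.copy()
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            return labels
        x = expression.to_numpy(dtype=float).T  # samples x genes
        eig = {m: _eigengene(x[:, labels == m]) for m in mods}
        best, best_d = None, np.inf
        for i, mi in enumerate(mods):
            for mj in mods[i + 1 :]:
                r = np.corrcoef(eig[mi], eig[mj])[0, 1]
                dis = 1.0 - r
                if dis < best_d:
                    best, best_d = (mi, mj), dis
        if best is None or best_d >= merge_cut:
            return labels
        labels[labels == best[1]] = best[0]


def _colwise_cor(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column of x with every column of y."""
    xs = x - x.mean(axis=0)
    ys = y - y.mean(axis=0)
    xn = np.sqrt((xs**2).sum(axis=0))
    yn = np.sqrt((ys**2).sum(axis=0))
    xn[xn == 0] = np.nan
    yn[yn == 0] = np.nan
    return np.clip((xs.T @ ys) / np.outer(xn, yn), -1.0, 1.0)


def _cor_with_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson r with its two-sided t-test p-value (df = n - 2)."""
    n = a.size
    if n < 3 or a.std() == 0 or b.std() == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(a, b)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), n - 2))


def module_significance(
    expression: pd.DataFrame,
    labels: pd.Series,
    traits: pd.DataFrame | pd.Series,
) -> ModuleSet:
    """Eigengenes, kME, gene significance and module-trait statistics.

    ``expression`` is genes x samples; ``traits`` numeric per-sample
    covariates (first column = the primary trait, e.g. disease state 1/0).
    A singleton module's eigengene is that gene standardized; its kME-GS
    correlation is reported as missing.
    """
    if isinstance(traits, pd.Series):
        traits = traits.to_frame()
    traits = traits.loc[expression.columns].astype(float)
    labels = labels.reindex(expression.index)
    x = expression.to_numpy(dtype=float).T  # samples x genes
    mods = sorted(set(labels) - {0})

    eig_rows = {}
    for m in mods:
        block = x[:, (labels == m).to_numpy()]
        eig_rows[f"ME{m}"] = _eigengene(block)
    eigengenes = pd.DataFrame(eig_rows, index=expression.columns).T

    # kME: gene x module correlation with the eigengenes
    kme = pd.DataFrame(
        _colwise_cor(x, eigengenes.to_numpy().T),
        index=expression.index,
        columns=eigengenes.index,
    )
    gs = pd.DataFrame(
        np.abs(_colwise_cor(x, traits.to_numpy())),
        index=expression.index,
        columns=traits.columns,
    )

    r_rows, p_rows = {}, {}
    for me in eigengenes.index:
        rr, pp = {}, {}
        for tr in traits.columns:
            rr[tr], pp[tr] = _cor_with_p(
                eigengenes.loc[me].to_numpy(), traits[tr].to_numpy()
            )
        r_rows[me], p_rows[me] = rr, pp
    module_trait_r = pd.DataFrame(r_rows).T
    module_trait_p = pd.DataFrame(p_rows).T

    primary = traits.columns[0]
    mm_rows = []
    for m in mods:
        members = (labels == m).to_numpy()
        if members.sum() < 3:
            cor, p = np.nan, np.nan
        else:
            cor, p = _cor_with_p(
                kme.loc[members, f"ME{m}"].abs().to_numpy(),
                gs.loc[members, primary].to_numpy(),
            )
        mm_rows.append(
            {
                "module": f"ME{m}",
                "size": int(members.sum()),
                "mm_gs_cor": cor,
                "mm_gs_p": p,
                "avg_GS": float(gs.loc[members, primary].mean()),
            }
        )
    mm_cols = ["module", "size", "mm_gs_cor", "mm_gs_p", "avg_GS"]
    mm_gs = pd.DataFrame(mm_rows, columns=mm_cols).set_index("module")
    return ModuleSet(
        labels=labels,
        eigengenes=eigengenes,
        kME=kme,
        GS=gs,
        module_trait_r=module_trait_r,
        module_trait_p=module_trait_p,
        mm_gs=mm_gs,
    )
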