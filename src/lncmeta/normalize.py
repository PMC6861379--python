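"""Transcript aggregation and TMM (trimmed mean of M-values) normalization.

Counts are normalized within each study with the classic TMM procedure
(doubly trimmed, precision-weighted mean of per-gene log-ratios against a
reference sample) and converted to log2 counts-per-million, the scale on
which all downstream effect sizes are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InputError, MappingError, NormalizationError

logger = logging.getLogger(__name__)

__all__ = [
    "StudyCounts",
    "NormalizedExpression",
    "aggregate_tx2gene",
    "tmm_factors",
    "log_cpm",
    "normalize_study",
    "read_counts_tsv",
    "read_tx2gene_tsv",
]


@dataclass
class StudyCounts:
    """One study's raw gene x sample count matrix plus its design.

    ``counts`` is a genes x samples DataFrame of non-negative integers;
    ``design`` has one row per sample column with at least a ``group``
    column in {"case", "control"}, plus ``study_id`` and ``tissue_class``.
    """

    study_id: str
    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise InputError(f"study {self.study_id}: negative counts")
        missing = set(self.counts.columns) ^ set(self.design.index)
        if missing:
            raise InputError(
                f"study {self.study_id}: design/sample mismatch: {sorted(missing)[:5]}"
            )
        groups = set(self.design["group"])
        if not {"case", "control"} <= groups:
            raise InputError(
                f"study {self.study_id}: need both case and control samples, got {groups}"
            )

    @property
    def case_samples(self) -> list[str]:
        return list(self.design.index[self.design["group"] == "case"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.design.index[self.design["group"] == "control"])


@dataclass
class NormalizedExpression:
    """TMM factors, effective library sizes and the logCPM matrix."""

    norm_factors: pd.Series
    effective_lib_sizes: pd.Series
    logcpm: pd.DataFrame = field(repr=False)


def aggregate_tx2gene(
    tx_counts: pd.DataFrame, tx2gene: pd.Series | dict, *, drop_unmapped: bool = False
) -> pd.DataFrame:
    """Sum transcript-level counts to gene level.

    ``tx2gene`` maps transcript id -> gene id. Unmapped transcripts raise
    a :class:`MappingError` naming the offenders unless ``drop_unmapped``.
    Column (per-sample) totals are preserved when every transcript maps.
    """
    mapping = pd.Series(tx2gene) if not isinstance(tx2gene, pd.Series) else tx2gene
    unmapped = tx_counts.index.difference(mapping.index)
    if len(unmapped):
        if not drop_unmapped:
            raise MappingError(
                f"{len(unmapped)} unmapped transcripts: {list(unmapped[:10])}"
            )
        logger.warning("dropping %d unmapped transcripts", len(unmapped))
        tx_counts = tx_counts.drop(index=unmapped)
    gene_ids = mapping.reindex(tx_counts.index)
    out = tx_counts.groupby(gene_ids.to_numpy()).sum()
    out.index.name = "gene_id"
    return out


def _quantile_over_libsize(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.array(
        [np.quantile(counts[:, j], p) / lib[j] for j in range(counts.shape[1])]
    )


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    """log2 scaling factor of one sample against the reference column."""
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos].astype(float), ref[pos].astype(float)
    if obs.size == 0:
        return 0.0
    m = np.log2((obs / lib_obs) / (ref / lib_ref))
    a = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
    # inverse of the asymptotic (binomial) variance of M
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample TMM normalization factors, geometric mean 1.

    The reference sample is the column whose 75th-percentile count fraction
    is closest to the mean of that quantity; each factor is 2^(weighted
    trimmed mean of M-values) against it, trimming 30% of genes by M and
    5% by A, weighted by inverse binomial variance.
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise NormalizationError("TMM requires at least two samples")
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        bad = list(counts.columns[lib <= 0])
        raise NormalizationError(f"all-zero samples: {bad}")
    q = _quantile_over_libsize(x, lib)
    ref_idx = int(np.argmin(np.abs(q - q.mean())))
    log_f = np.array(
        [_tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx]) for j in range(x.shape[1])]
    )
    factors = 2.0 ** log_f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def log_cpm(
    counts: pd.DataFrame, factors: pd.Series | None = None, prior_count: float = 0.5
) -> NormalizedExpression:
    """log2 counts-per-million on TMM-effective library sizes.

    logcpm[g, j] = log2((count + prior) / (lib_j * factor_j + 2 * prior) * 1e6).
    """
    if prior_count <= 0:
        raise InputError(f"prior_count must be positive, got {prior_count}")
    if factors is None:
        factors = tmm_factors(counts)
    factors = factors.reindex(counts.columns)
    lib = counts.sum(axis=0).astype(float)
    eff = lib * factors
    logcpm = np.log2(
        (counts.to_numpy(dtype=float) + prior_count)
        / (eff.to_numpy() + 2.0 * prior_count)
        * 1e6
    )
    return NormalizedExpression(
        norm_factors=factors,
        effective_lib_sizes=eff.rename("effective_lib_size"),
        logcpm=pd.DataFrame(logcpm, index=counts.index, columns=counts.columns),
    )


def normalize_study(study: StudyCounts, prior_count: float = 0.5) -> NormalizedExpression:
    """TMM + logCPM for one study (the within-study normalization path)."""
    return log_cpm(study.counts, tmm_factors(study.counts), prior_count)


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a genes x samples count TSV (first column = gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_tx2gene_tsv(path) -> pd.Series:
    """Read a two-column transcript_id/gene_id TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.iloc[0, 0].lower() in {"transcript_id", "transcript", "tx_id", "txid"}:
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise MappingError(f"{path}: expected two tab-separated columns")
    dup = df[0].duplicated()
    if dup.any():
        raise MappingError(f"{path}: transcripts mapped more than once: {list(df[0][dup][:5])}")
    return pd.Series(df[1].to_numpy(), index=df[0].to_numpy(), name="gene_id")
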