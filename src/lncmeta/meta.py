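"""Per-gene effect sizes and heterogeneity-aware meta-analysis.

For every gene the pipeline computes a standardized mean difference
(Hedges' g) between cases and controls in each study, tests between-study
heterogeneity with Cochran's Q / I-squared, pools with a fixed-effects
(inverse variance) model unless heterogeneity is significant (I2 > 50 and
p_Q < 0.01), in which case a DerSimonian-Laird random-effects model is
used, and calls differential expression when the 95% CI excludes zero and
the Benjamini-Hochberg FDR is below 0.05.  An adaptively weighted Fisher
combination of the per-study p-values is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, InsufficientStudiesError, PipelineError
from .normalize import StudyCounts, normalize_study

logger = logging.getLogger(__name__)

__all__ = [
    "GeneEffect",
    "MetaConfig",
    "hedges_g",
    "study_effects",
    "cochran_q",
    "pool_fixed",
    "pool_random",
    "aw_fisher",
    "bh_fdr",
    "run_meta",
]

Z95 = 1.959963984540054  # standard normal 97.5% quantile for 95% CIs


@dataclass
class GeneEffect:
    """One study's standardized mean difference for one gene."""

    study_id: str
    y: float  # Hedges' g
    v: float  # variance of y
    n_case: int
    n_control: int
    p_study: float  # two-sided Welch-t p-value


@dataclass
class MetaConfig:
    """Thresholds and options of the meta-analytic stage."""

    i2_threshold: float = 50.0
    p_q_threshold: float = 0.01
    fdr_threshold: float = 0.05
    prior_count: float = 0.5
    scale: str = "logcpm"  # or "cpm": SMD on un-logged counts per million
    aw_permutations: int = 50
    min_studies: int = 2
    seed: int = 0


def hedges_g(case_values, control_values, study_id: str = "") -> GeneEffect:
    """Hedges' g with its variance and a Welch-t per-study p-value.

    g = J * (mean_case - mean_control) / s_pooled with the small-sample
    correction J = 1 - 3/(4*(n1+n2-2) - 1);
    v = (n1+n2)/(n1*n2) + g^2 / (2*(n1+n2)).
    """
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    n1, n2 = case.size, ctrl.size
    if n1 < 2 or n2 < 2:
        raise InputError(f"need >=2 values per arm, got {n1}/{n2}")
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * case.var(ddof=1) + (n2 - 1) * ctrl.var(ddof=1)) / df
    if s2 <= 0:
        raise InputError("zero pooled SD: degenerate gene")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    d = (case.mean() - ctrl.mean()) / np.sqrt(s2)
    g = j * d
    v = (n1 + n2) / (n1 * n2) + g * g / (2.0 * (n1 + n2))
    if case.var(ddof=1) > 0 or ctrl.var(ddof=1) > 0:
        p = float(stats.ttest_ind(case, ctrl, equal_var=False).pvalue)
    else:  # equal constant arms cannot happen here (s2 > 0); unequal ones give p ~ 0
        p = 0.0
    return GeneEffect(study_id, float(g), float(v), n1, n2, p)


def _welch_p(m1, v1, n1, m2, v2, n2):
    """Vectorized two-sided Welch t-test p-value."""
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(se2 > 0, p, 1.0)
    return np.clip(p, np.nextafter(0.0, 1.0), 1.0)


def study_effects(expr: pd.DataFrame, case_mask: np.ndarray) -> pd.DataFrame:
    """Vectorized per-gene Hedges' g over one study's expression matrix.

    ``expr`` is genes x samples on the analysis scale; ``case_mask`` marks
    case columns.  Genes with zero pooled SD come back as NaN rows
    (degenerate, to be excluded downstream).
    """
    x = expr.to_numpy(dtype=float)
    case, ctrl = x[:, case_mask], x[:, ~case_mask]
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise InputError(f"need >=2 samples per arm, got {n1}/{n2}")
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    v1, v2 = case.var(axis=1, ddof=1), ctrl.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = j * (m1 - m2) / np.sqrt(s2)
    g = np.where(s2 > 0, g, np.nan)
    v = (n1 + n2) / (n1 * n2) + g * g / (2.0 * (n1 + n2))
    p = _welch_p(m1, v1, n1, m2, v2, n2)
    p = np.where(s2 > 0, p, np.nan)
    n_deg = int(np.isnan(g).sum())
    if n_deg:
        logger.info("%d degenerate genes (zero pooled SD) excluded", n_deg)
    return pd.DataFrame(
        {"y": g, "v": v, "p_study": p, "n_case": n1, "n_control": n2},
        index=expr.index,
    )


def _as_arrays(effects) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(effects, pd.DataFrame):
        return effects["y"].to_numpy(float), effects["v"].to_numpy(float)
    y = np.array([e.y for e in effects], dtype=float)
    v = np.array([e.v for e in effects], dtype=float)
    return y, v


def cochran_q(effects) -> tuple[float, int, float, float]:
    """Cochran's Q with its chi-square p-value and I2 (percent).

    Returns (Q, df, p_Q, I2) with I2 = max(0, (Q - df)/Q) * 100.
    """
    y, v = _as_arrays(effects)
    k = y.size
    if k < 2:
        raise InsufficientStudiesError(f"Q needs >=2 studies, got {k}")
    w = 1.0 / v
    ybar = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - ybar) ** 2))
    df = k - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0
    return q, df, p_q, i2


def pool_fixed(effects) -> tuple[float, float, float, float, float]:
    """Inverse-variance fixed-effects pooling: (smd, ci_low, ci_high, z, p)."""
    y, v = _as_arrays(effects)
    if y.size < 2:
        raise InsufficientStudiesError("fixed-effects pooling needs >=2 studies")
    w = 1.0 / v
    pooled = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = pooled / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return pooled, pooled - Z95 * se, pooled + Z95 * se, z, p


def pool_random(effects) -> tuple[float, float, float, float, float, float]:
    """DerSimonian-Laird random-effects pooling.

    tau2 = max(0, (Q - df)/C) with C = sum(w) - sum(w^2)/sum(w); studies are
    re-weighted by 1/(v + tau2).  Returns (tau2, smd, ci_low, ci_high, z, p);
    collapses exactly to :func:`pool_fixed` when Q <= df.
    """
    y, v = _as_arrays(effects)
    if y.size < 2:
        raise InsufficientStudiesError("random-effects pooling needs >=2 studies")
    q, df, _, _ = cochran_q(effects)
    w = 1.0 / v
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    ws = 1.0 / (v + tau2)
    pooled = float(np.sum(ws * y) / np.sum(ws))
    se = float(np.sqrt(1.0 / np.sum(ws)))
    z = pooled / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return tau2, pooled, pooled - Z95 * se, pooled + Z95 * se, z, p


def aw_fisher(p_values) -> tuple[float, np.ndarray]:
    """Adaptively weighted Fisher statistic and its optimal study weights.

    For a binary weight vector w, U(w) = -2 * sum_i w_i * ln p_i has a
    chi-square upper tail s(w) on 2*|w| df; the minimizer over all 2^k - 1
    vectors always selects the m smallest p-values for some m, so only k
    candidates are scanned.  Returns (min_m s(w_m), best weight vector).
    The raw minimum is anti-conservative as a p-value; calibrate it by
    permutation (see :func:`run_meta`) before thresholding it.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise InputError("aw_fisher needs at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in (0, 1]")
    if (p == 0).any():
        logger.warning("p = 0 clipped to smallest positive float")
        p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    order = np.argsort(p, kind="stable")
    u = -2.0 * np.cumsum(np.log(p[order]))
    m = np.arange(1, p.size + 1)
    s = stats.chi2.sf(u, 2 * m)
    best = int(np.argmin(s))
    weights = np.zeros(p.size, dtype=int)
    weights[order[: best + 1]] = 1
    return float(s[best]), weights


def _aw_stat_matrix(p: np.ndarray) -> np.ndarray:
    """Row-wise AW-Fisher minimum statistic for a genes x studies p matrix.

    NaN entries (gene absent from a study) are ignored.
    """
    ps = np.sort(np.where(np.isfinite(p), p, np.inf), axis=1)
    ps = np.clip(ps, np.nextafter(0.0, 1.0), None)
    k = np.isfinite(p).sum(axis=1)
    out = np.full(p.shape[0], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(ps <= 1.0, np.log(ps), 0.0)
        u = -2.0 * np.cumsum(logp, axis=1)
        m = np.arange(1, p.shape[1] + 1)
        s = stats.chi2.sf(u, 2 * m)
    s = np.where(np.arange(p.shape[1]) < k[:, None], s, np.inf)
    valid = k >= 1
    out[valid] = s[valid].min(axis=1)
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise InputError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _study_logexpr(study: StudyCounts, config: MetaConfig) -> pd.DataFrame:
    norm = normalize_study(study, config.prior_count)
    if config.scale == "logcpm":
        return norm.logcpm
    if config.scale == "cpm":
        return pd.DataFrame(
            2.0 ** norm.logcpm.to_numpy(), index=norm.logcpm.index, columns=norm.logcpm.columns
        )
    raise InputError(f"unknown scale {config.scale!r}")


def run_meta(
    studies: list[StudyCounts], config: MetaConfig | None = None
) -> pd.DataFrame:
    """Full per-gene meta-analysis over a list of studies.

    Within each study: TMM -> logCPM -> vectorized Hedges' g.  Across
    studies: Cochran's Q / I2, REM iff (I2 > 50 and p_Q < 0.01) else FEM,
    95% CI, BH-FDR over the pooled p-values, AW-Fisher with permutation
    calibration pooled across genes.  Genes present in fewer than two
    studies are reported untested with a reason code.

    Returns one row per gene with all MetaResult fields.
    """
    config = config or MetaConfig()
    if not studies:
        raise PipelineError("meta: no studies supplied")
    exprs, masks, effects = [], [], []
    for st in studies:
        expr = _study_logexpr(st, config)
        mask = (st.design.loc[expr.columns, "group"] == "case").to_numpy()
        exprs.append(expr)
        masks.append(mask)
        eff = study_effects(expr, mask)
        eff["study_id"] = st.study_id
        effects.append(eff)

    genes = exprs[0].index
    for e in exprs[1:]:
        genes = genes.union(e.index)
    if len(genes) == 0:
        raise PipelineError("meta: no genes shared across studies")
    k_total = len(studies)
    y = np.full((len(genes), k_total), np.nan)
    v = np.full_like(y, np.nan)
    p_st = np.full_like(y, np.nan)
    for i, eff in enumerate(effects):
        sub = eff.reindex(genes)
        y[:, i] = sub["y"].to_numpy()
        v[:, i] = sub["v"].to_numpy()
        p_st[:, i] = sub["p_study"].to_numpy()

    res = _meta_from_effect_matrix(y, v, config)
    res.index = genes
    res.index.name = "gene_id"

    res["aw_stat"] = _aw_stat_matrix(p_st)
    if config.aw_permutations > 0:
        res["aw_p"] = _aw_permutation_p(
            exprs, masks, res["aw_stat"].to_numpy(), config
        )
    else:
        logger.warning(
            "aw_permutations=0: reporting the raw AW minimum as aw_p; "
            "it is anti-conservative"
        )
        res["aw_p"] = res["aw_stat"]
    aw_w = []
    for row in p_st:
        finite = np.isfinite(row)
        if finite.sum() == 0:
            aw_w.append("")
            continue
        _, w = aw_fisher(row[finite])
        ids = np.array([studies[i].study_id for i in np.flatnonzero(finite)])
        aw_w.append(",".join(ids[w == 1]))
    res["aw_weights"] = aw_w
    return res


def _meta_from_effect_matrix(
    y: np.ndarray, v: np.ndarray, config: MetaConfig
) -> pd.DataFrame:
    """Heterogeneity test, FEM/REM pooling and DE calls from (y, v) matrices."""
    finite = np.isfinite(y) & np.isfinite(v)
    k = finite.sum(axis=1)
    w = np.where(finite, 1.0 / v, 0.0)
    sw = w.sum(axis=1)
    yz = np.where(finite, y, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ybar = (w * yz).sum(axis=1) / sw
        q = (w * (yz - ybar[:, None]) ** 2 * finite).sum(axis=1)
        df = k - 1
        p_q = stats.chi2.sf(q, np.maximum(df, 1))
        i2 = np.where(q > 0, np.maximum(0.0, (q - df) / np.maximum(q, 1e-300)) * 100.0, 0.0)
        c = sw - (w**2).sum(axis=1) / sw
        tau2 = np.where(c > 0, np.maximum(0.0, (q - df) / np.where(c > 0, c, 1.0)), 0.0)

    use_rem = (i2 > config.i2_threshold) & (p_q < config.p_q_threshold)
    tau2_used = np.where(use_rem, tau2, 0.0)
    ws = np.where(finite, 1.0 / (v + tau2_used[:, None]), 0.0)
    sws = ws.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = (ws * yz).sum(axis=1) / sws
        se = np.sqrt(1.0 / sws)
    z = pooled / se
    p_meta = 2.0 * stats.norm.sf(np.abs(z))

    tested = k >= config.min_studies
    fdr = np.full(y.shape[0], np.nan)
    if tested.any():
        fdr[tested] = bh_fdr(p_meta[tested])
    ci_low = pooled - Z95 * se
    ci_high = pooled + Z95 * se
    excludes_zero = (ci_low > 0) | (ci_high < 0)
    de_call = tested & excludes_zero & (fdr < config.fdr_threshold)
    direction = np.where(de_call & (pooled > 0), "up", np.where(de_call, "down", "none"))

    out = pd.DataFrame(
        {
            "k": k,
            "Q": np.where(tested, q, np.nan),
            "df": np.where(tested, df, np.nan),
            "p_Q": np.where(tested, p_q, np.nan),
            "I2": np.where(tested, i2, np.nan),
            "tau2": np.where(tested, tau2_used, np.nan),
            "model": np.where(~tested, "untested", np.where(use_rem, "REM", "FEM")),
            "smd_pooled": np.where(tested, pooled, np.nan),
            "ci_low": np.where(tested, ci_low, np.nan),
            "ci_high": np.where(tested, ci_high, np.nan),
            "z": np.where(tested, z, np.nan),
            "p_meta": np.where(tested, p_meta, np.nan),
            "fdr": fdr,
            "de_call": de_call,
            "direction": direction,
            "reason": np.where(tested, "", "insufficient_studies"),
        }
    )
    return out


def _aw_permutation_p(
    exprs: list[pd.DataFrame],
    case_masks: list[np.ndarray],
    observed: np.ndarray,
    config: MetaConfig,
) -> np.ndarray:
    """Permutation calibration of the AW minimum statistic.

    Group labels are permuted within each study; the null minima are pooled
    across genes and permutations, and each gene's p-value is the fraction
    of the pooled null at or below its observed minimum.
    """
    rng = np.random.default_rng(config.seed)
    genes = exprs[0].index
    for e in exprs[1:]:
        genes = genes.union(e.index)
    null: list[np.ndarray] = []
    for _ in range(config.aw_permutations):
        p_null = np.full((len(genes), len(exprs)), np.nan)
        for i, (expr, mask) in enumerate(zip(exprs, case_masks)):
            perm = rng.permutation(mask)
            eff = study_effects(expr, perm)
            p_null[:, i] = eff["p_study"].reindex(genes).to_numpy()
        null.append(_aw_stat_matrix(p_null))
    pool = np.concatenate(null)
    pool = pool[np.isfinite(pool)]
    pool.sort()
    out = np.full(observed.shape, np.nan)
    ok = np.isfinite(observed)
    ranks = np.searchsorted(pool, observed[ok], side="right")
    out[ok] = (1.0 + ranks) / (1.0 + pool.size)
    return out


def forest_data(studies: list[StudyCounts], gene_id: str, config: MetaConfig | None = None) -> pd.DataFrame:
    """Per-study effect, variance and 95% CI for one gene (forest-plot table)."""
    config = config or MetaConfig()
    rows = []
    for st in studies:
        if gene_id not in st.counts.index:
            continue
        expr = _study_logexpr(st, config)
        mask = (st.design.loc[expr.columns, "group"] == "case").to_numpy()
        eff = study_effects(expr, mask).loc[gene_id]
        se = np.sqrt(eff["v"])
        rows.append(
            {
                "study_id": st.study_id,
                "y": eff["y"],
                "v": eff["v"],
                "ci_low": eff["y"] - Z95 * se,
                "ci_high": eff["y"] + Z95 * se,
                "n_case": int(eff["n_case"]),
                "n_control": int(eff["n_control"]),
            }
        )
    return pd.DataFrame(rows)
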