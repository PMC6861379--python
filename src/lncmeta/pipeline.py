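"""End-to-end orchestration: simulate/load -> normalize -> meta-analysis
(whole cohort and subgroups) -> DE-set overlap -> tissue specificity ->
co-expression modules -> enrichment, with a reproducibility manifest.

Every stage writes plain TSV artifacts into the output directory and the
manifest records their SHA-256 hashes, the seed and the package version,
so a rerun with the same configuration and seed yields identical hashes.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enrich import ora, read_gmt
from .errors import ConfigurationError, PipelineError
from .meta import MetaConfig, run_meta
from .network import (
    NetworkConfig,
    adjacency_matrix,
    detect_modules,
    module_significance,
    pick_soft_threshold,
    remove_outlier_samples,
    tom_matrix,
)
from .normalize import StudyCounts, aggregate_tx2gene, normalize_study, read_counts_tsv, read_tx2gene_tsv
from .simulate import (
    SimulationConfig,
    generate_gene_sets,
    generate_multistudy_counts,
    generate_tissue_atlas,
    write_studies,
    write_truth,
)
from .specificity import cluster_genes, specificity_scores

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "de_overlap", "load_studies"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and options of a full pipeline run.

    Either ``simulate`` is set (synthetic inputs are generated in the
    output directory) or ``study_paths``/``design_path`` point at count
    and design TSVs on disk.  ``subgroup_key`` names the design column
    used for subgroup meta-analyses (default tissue_class).
    """

    outdir: str = "results/pipeline"
    simulate: SimulationConfig | None = None
    study_paths: tuple = ()
    design_path: str | None = None
    tx2gene_path: str | None = None
    atlas_path: str | None = None
    gmt_path: str | None = None
    subgroup_key: str = "tissue_class"
    meta: MetaConfig = field(default_factory=MetaConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    enrich_adj_threshold: float = 0.05
    module_p_cutoff: float = 0.05  # both significance indices must beat this
    max_network_genes: int = 500
    atlas_tissues: tuple = ("brain", "blood", "heart", "liver", "lung", "muscle")
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load a YAML or JSON configuration file."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulate", None)
        meta = raw.pop("meta", None)
        net = raw.pop("network", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimulationConfig(**sim)
        if meta is not None:
            cfg.meta = MetaConfig(**meta)
        if net is not None:
            cfg.network = NetworkConfig(**net)
        return cfg


def load_studies(study_paths, design_path) -> list[StudyCounts]:
    """Assemble StudyCounts objects from count TSVs plus a shared design TSV."""
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    studies = []
    for p in study_paths:
        counts = read_counts_tsv(p)
        sub = design.loc[design.index.intersection(counts.columns)]
        if sub.empty:
            raise PipelineError(f"load: no design rows for samples of {p}")
        sid = str(sub["study_id"].iloc[0])
        studies.append(StudyCounts(study_id=sid, counts=counts[sub.index], design=sub))
    return studies


def de_overlap(de_sets: dict) -> pd.DataFrame:
    """Venn-region counts of named DE gene-id sets.

    Returns one row per non-empty combination of set names with the count
    of genes exactly in that region, plus, for each named set, the
    percentage of the set that the region represents.
    """
    if len(de_sets) < 2:
        raise PipelineError("overlap needs at least two sets")
    names = list(de_sets)
    for n, s in de_sets.items():
        if not s:
            logger.warning("overlap: set %s is empty", n)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(set(de_sets[n]) for n in combo))
            outside = set.union(
                set(), *(set(de_sets[n]) for n in names if n not in combo)
            )
            region = inside - outside
            row = {"region": "&".join(combo), "count": len(region)}
            for n in names:
                row[f"pct_of_{n}"] = (
                    100.0 * len(region) / len(de_sets[n]) if de_sets[n] else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _combined_zscored_matrix(studies: list[StudyCounts], genes, meta_cfg: MetaConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Study-wise logCPM z-scored per gene, concatenated across studies."""
    blocks, designs = [], []
    for st in studies:
        expr = normalize_study(st, meta_cfg.prior_count).logcpm.reindex(genes)
        x = expr.to_numpy(dtype=float)
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        blocks.append(pd.DataFrame((x - mu) / sd, index=expr.index, columns=expr.columns))
        designs.append(st.design)
    return pd.concat(blocks, axis=1), pd.concat(designs)


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest.

    Writes, under ``config.outdir``: the simulated inputs (if any),
    per-run meta-analysis TSVs (whole cohort and each subgroup level),
    the Venn overlap table of DE sets, tissue-specificity scores and the
    Manhattan-distance cluster tables, network module labels, eigengenes,
    module-trait statistics, kME/GS tables, per-module enrichment TSVs,
    and ``manifest.json``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
        "artifact_hashes": {},
    }
    artifacts: list[Path] = []

    def _stage(name):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        # ------------------------------------------------ simulate / load
        if config.simulate is not None:
            _stage("simulate")
            studies, truth = generate_multistudy_counts(config.simulate)
            datadir = out / "data"
            paths = write_studies(studies, datadir)
            write_truth(truth, datadir / "truth.json")
            atlas, atlas_truth = generate_tissue_atlas(
                config.simulate.n_genes,
                list(config.atlas_tissues),
                frac_specific=0.3,
                seed=config.seed + 1,
            )
            atlas.to_csv(datadir / "atlas.tsv", sep="\t")
            artifacts += [Path(p) for p in paths["counts"].values()]
            artifacts += [Path(paths["design"]), datadir / "truth.json", datadir / "atlas.tsv"]
        else:
            _stage("load")
            if not config.study_paths or config.design_path is None:
                raise ConfigurationError("need study_paths and design_path (or simulate)")
            for p in [*config.study_paths, config.design_path, config.atlas_path, config.gmt_path]:
                if p is not None and not Path(p).exists():
                    raise ConfigurationError(f"missing input file: {p}")
            studies = load_studies(config.study_paths, config.design_path)
            atlas = (
                pd.read_csv(config.atlas_path, sep="\t", index_col=0)
                if config.atlas_path
                else None
            )

        if config.tx2gene_path:
            _stage("aggregate")
            t2g = read_tx2gene_tsv(config.tx2gene_path)
            studies = [
                StudyCounts(st.study_id, aggregate_tx2gene(st.counts, t2g), st.design)
                for st in studies
            ]

        # ------------------------------------------------ meta-analysis
        _stage("meta")
        meta_cfg = config.meta
        runs = {"whole": run_meta(studies, meta_cfg)}
        levels = sorted(
            {str(v) for st in studies for v in st.design[config.subgroup_key]}
        )
        for level in levels:
            sub = [
                st
                for st in studies
                if (st.design[config.subgroup_key] == level).all()
            ]
            if len(sub) >= 2:
                runs[level] = run_meta(sub, meta_cfg)
        for name, res in runs.items():
            p = out / f"meta_{name}.tsv"
            res.to_csv(p, sep="\t")
            artifacts.append(p)

        # ------------------------------------------------ DE overlap
        _stage("overlap")
        de_sets = {
            name: list(res.index[res["de_call"]]) for name, res in runs.items()
        }
        if len(de_sets) >= 2:
            overlap = de_overlap(de_sets)
            p = out / "de_overlap.tsv"
            overlap.to_csv(p, sep="\t", index=False)
            artifacts.append(p)

        # ------------------------------------------------ tissue specificity
        whole = runs["whole"]
        de_genes = list(whole.index[whole["de_call"]])
        if atlas is not None:
            _stage("specificity")
            scores = specificity_scores(atlas)
            p = out / "specificity_scores.tsv"
            scores.to_csv(p, sep="\t")
            artifacts.append(p)
            de_in_atlas = [g for g in de_genes if g in atlas.index]
            if len(de_in_atlas) >= 2:
                z, leaves = cluster_genes(atlas.loc[de_in_atlas])
                merge = pd.DataFrame(z, columns=["left", "right", "height", "size"])
                merge.to_csv(out / "de_cluster_merges.tsv", sep="\t", index=False)
                pd.Series(leaves, name="gene_id").to_csv(
                    out / "de_cluster_leaf_order.tsv", sep="\t", index=False
                )
                artifacts += [out / "de_cluster_merges.tsv", out / "de_cluster_leaf_order.tsv"]

        # ------------------------------------------------ co-expression
        _stage("network")
        net_genes = de_genes
        if len(net_genes) < 20:
            logger.warning(
                "only %d DE genes; topping up with the smallest meta p-values",
                len(net_genes),
            )
            net_genes = list(
                whole.sort_values("p_meta").index[: max(50, len(net_genes))]
            )
        if len(net_genes) > config.max_network_genes:
            ranked = whole.loc[net_genes].sort_values("p_meta")
            net_genes = list(ranked.index[: config.max_network_genes])
        expr, design_all = _combined_zscored_matrix(studies, net_genes, meta_cfg)
        expr, removed = remove_outlier_samples(expr, config.network)
        design_all = design_all.loc[expr.columns]
        beta, fit = pick_soft_threshold(expr, config.network)
        fit.to_csv(out / "soft_threshold_fit.tsv", sep="\t", index=False)
        adj = adjacency_matrix(expr, beta)
        tom = tom_matrix(adj)
        labels = detect_modules(tom, config.network, expression=expr)
        traits = pd.DataFrame(
            {"disease": (design_all["group"] == "case").astype(float)},
            index=design_all.index,
        )
        if config.subgroup_key in design_all:
            lv = sorted(set(design_all[config.subgroup_key]))
            if len(lv) == 2:
                traits[config.subgroup_key] = (
                    design_all[config.subgroup_key] == lv[0]
                ).astype(float)
        modules = module_significance(expr, labels, traits)
        labels.to_frame().to_csv(out / "module_labels.tsv", sep="\t")
        modules.eigengenes.to_csv(out / "module_eigengenes.tsv", sep="\t")
        modules.module_trait_r.to_csv(out / "module_trait_r.tsv", sep="\t")
        modules.module_trait_p.to_csv(out / "module_trait_p.tsv", sep="\t")
        modules.kME.to_csv(out / "module_kME.tsv", sep="\t")
        modules.GS.to_csv(out / "gene_significance.tsv", sep="\t")
        modules.mm_gs.to_csv(out / "module_mm_gs.tsv", sep="\t")
        artifacts += [
            out / "soft_threshold_fit.tsv",
            out / "module_labels.tsv",
            out / "module_eigengenes.tsv",
            out / "module_trait_r.tsv",
            out / "module_trait_p.tsv",
            out / "module_kME.tsv",
            out / "gene_significance.tsv",
            out / "module_mm_gs.tsv",
        ]

        # ------------------------------------------------ enrichment
        _stage("enrich")
        if config.gmt_path:
            collection = read_gmt(config.gmt_path, universe=labels.index)
        else:
            # synthetic demo wiring: plant sets inside the detected modules
            collection, _ = generate_gene_sets(
                labels, n_sets=30, enrichment_strength=0.8, seed=config.seed + 2
            )
        top = _top_modules(modules, config.module_p_cutoff)
        enrich_paths = []
        for me in top:
            m = int(me.removeprefix("ME"))
            members = list(labels.index[labels == m])
            if len(members) < 3:
                continue
            rows = ora(
                members,
                collection,
                min_set=5,
                max_set=500,
                adj_threshold=config.enrich_adj_threshold,
            )
            p = out / f"enrichment_{me}.tsv"
            rows.to_csv(p, sep="\t", index=False)
            enrich_paths.append(p)
        artifacts += enrich_paths
        manifest["top_modules"] = list(top)
        manifest["removed_outliers"] = removed
        manifest["beta"] = int(beta)
        manifest["n_de_genes"] = len(de_genes)
    except Exception as exc:
        stage = manifest["stages"][-1] if manifest["stages"] else "init"
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    for p in artifacts:
        manifest["artifact_hashes"][str(p.relative_to(out))] = _sha256(p)
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _top_modules(modules, p_cutoff: float) -> list[str]:
    """Modules passing both significance indices, ranked by average GS."""
    if modules.module_trait_p.empty:
        return []
    primary = modules.module_trait_p.columns[0]
    ok = []
    for me in modules.module_trait_p.index:
        p_trait = modules.module_trait_p.loc[me, primary]
        p_mmgs = modules.mm_gs.loc[me, "mm_gs_p"] if me in modules.mm_gs.index else np.nan
        if np.isfinite(p_trait) and p_trait < p_cutoff and np.isfinite(p_mmgs) and p_mmgs < p_cutoff:
            ok.append(me)
    if not ok:  # fall back to the single most trait-associated module
        ok = [modules.module_trait_p[primary].idxmin()]
    return sorted(ok, key=lambda me: -modules.mm_gs.loc[me, "avg_GS"])
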