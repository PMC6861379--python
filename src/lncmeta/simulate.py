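"""Synthetic multi-study RNA-seq data with known ground truth.

The generator emulates the data model assumed by the downstream stages: a
collection of case/control studies of very unequal size, negative-binomial
gene counts with per-sample library sizes, per-gene case effects planted
in standardized units with optional between-study heterogeneity, a tissue
atlas with one-tissue-dominant genes, latent-factor module structure tied
to a binary trait, and gene-set collections enriched in planted modules.
Everything is driven by a single integer seed and is bit-reproducible.

Planted effects are specified as standardized mean differences (SMD) and
converted internally to per-gene log2 fold changes through the
delta-method standard deviation of log counts, sqrt(1/mu + phi)/ln 2, so
the true SMD on the logCPM analysis scale equals the requested ``delta``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .normalize import StudyCounts

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "generate_multistudy_counts",
    "generate_tissue_atlas",
    "generate_coexpression_data",
    "generate_gene_sets",
    "write_studies",
    "write_truth",
]

LN2 = np.log(2.0)

# Study-arm size envelope of the emulated compendium: ~20 studies whose case
# arms range from 3 to 58 samples and control arms from 3 to 234.
CASE_RANGE = (3, 58)
CONTROL_RANGE = (3, 234)


@dataclass
class SimulationConfig:
    """Conditions of one multi-study simulation.

    ``delta`` is the true standardized effect (SMD) of differentially
    expressed genes on the log2 expression scale; ``tau2`` the
    between-study variance of that standardized effect; ``nb_dispersion``
    the NB dispersion phi (variance = mu + phi * mu^2).  When
    ``study_sizes`` is None, per-study case/control arm sizes are drawn
    log-uniformly over the compendium envelope (3-58 cases, 3-234
    controls per study).
    """

    n_studies: int = 20
    n_genes: int = 2000
    study_sizes: tuple | None = None  # ((n_case, n_control), ...) per study
    frac_de: float = 0.1
    frac_up: float = 0.5  # fraction of DE genes regulated upward in cases
    delta: float = 0.6
    tau2: float = 0.02
    nb_dispersion: float = 0.1
    lib_size_range: tuple = (500_000, 2_000_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies <= 0 or self.n_genes <= 0:
            raise ConfigurationError("n_studies and n_genes must be positive")
        if not (0.0 <= self.frac_de <= 1.0):
            raise ConfigurationError("frac_de must lie in [0, 1]")
        if not (0.0 <= self.frac_up <= 1.0):
            raise ConfigurationError("frac_up must lie in [0, 1]")
        if self.tau2 < 0:
            raise ConfigurationError("tau2 must be non-negative")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        lo, hi = self.lib_size_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("lib_size_range must be positive and ordered")
        if self.study_sizes is not None:
            if len(self.study_sizes) != self.n_studies:
                raise ConfigurationError("study_sizes length must equal n_studies")
            for nc, nn in self.study_sizes:
                if nc <= 0 or nn <= 0:
                    raise ConfigurationError("arm sizes must be positive")


@dataclass
class SimulationTruth:
    """Ground truth of a simulation run."""

    de_flags: pd.Series = field(default_factory=pd.Series)
    true_effects: pd.DataFrame = field(default_factory=pd.DataFrame)  # genes x studies, SMD units
    specific_tissue: pd.Series = field(default_factory=pd.Series)
    module_labels: pd.Series = field(default_factory=pd.Series)
    enriched_sets: list = field(default_factory=list)


def _draw_sizes(rng: np.random.Generator, n_studies: int) -> list[tuple[int, int]]:
    cases = np.exp(rng.uniform(np.log(CASE_RANGE[0]), np.log(CASE_RANGE[1]), n_studies))
    ctrls = np.exp(rng.uniform(np.log(CONTROL_RANGE[0]), np.log(CONTROL_RANGE[1]), n_studies))
    return [(int(round(c)), int(round(n))) for c, n in zip(cases, ctrls)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Gamma-Poisson negative binomial with variance mu + phi * mu^2."""
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def generate_multistudy_counts(
    config: SimulationConfig,
) -> tuple[list[StudyCounts], SimulationTruth]:
    """Simulate per-study NB count matrices with planted standardized effects.

    For sample j of study i and gene g the NB mean is
    s_j * q_g * 2^(x_j * lfc_gi) with x_j the case indicator, library size
    s_j log-uniform over ``lib_size_range``, relative abundance q_g
    log-normal, and lfc_gi = (delta_g + b_gi) * sqrt(1/mu_g + phi)/ln 2
    where b_gi ~ N(0, tau2) is the between-study perturbation.  The truth
    records DE flags and the realized standardized effect of every gene in
    every study.
    """
    rng = np.random.default_rng(config.seed)
    genes = pd.Index([f"g{i:05d}" for i in range(config.n_genes)], name="gene_id")
    sizes = (
        list(config.study_sizes)
        if config.study_sizes is not None
        else _draw_sizes(rng, config.n_studies)
    )

    # relative abundances, normalized; typical mean counts span ~2 decades
    q = np.exp(rng.normal(0.0, 1.0, config.n_genes))
    q = q / q.sum()
    nominal_lib = np.exp(np.mean(np.log(config.lib_size_range)))
    mu0 = q * nominal_lib  # baseline mean count at the nominal depth
    sd_log2 = np.sqrt(1.0 / mu0 + config.nb_dispersion) / LN2

    n_de = int(round(config.frac_de * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    n_up = int(round(config.frac_up * n_de))
    signs = np.concatenate([np.ones(n_up), -np.ones(n_de - n_up)])
    delta_g = np.zeros(config.n_genes)
    delta_g[de_idx] = config.delta * signs
    de_flags = pd.Series(delta_g != 0, index=genes, name="is_de")

    studies: list[StudyCounts] = []
    study_ids = [f"study{i + 1:02d}" for i in range(len(sizes))]
    effects = np.zeros((config.n_genes, len(sizes)))
    for i, (sid, (n_case, n_ctrl)) in enumerate(zip(study_ids, sizes)):
        b = (
            rng.normal(0.0, np.sqrt(config.tau2), config.n_genes)
            if config.tau2 > 0
            else np.zeros(config.n_genes)
        )
        std_effect = delta_g + b
        effects[:, i] = std_effect
        lfc = std_effect * sd_log2
        n_samp = n_case + n_ctrl
        x = np.concatenate([np.ones(n_case), np.zeros(n_ctrl)])
        s = np.exp(
            rng.uniform(
                np.log(config.lib_size_range[0]),
                np.log(config.lib_size_range[1]),
                n_samp,
            )
        )
        mean = np.outer(q, s) * 2.0 ** (lfc[:, None] * x[None, :])
        counts = _nb_draw(rng, mean, config.nb_dispersion)
        sample_ids = [f"{sid}_s{j:03d}" for j in range(n_samp)]
        tissue = "brain" if i % 2 == 0 else "blood"
        design = pd.DataFrame(
            {
                "group": np.where(x == 1, "case", "control"),
                "study_id": sid,
                "tissue_class": tissue,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        studies.append(
            StudyCounts(
                study_id=sid,
                counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
                design=design,
            )
        )
    truth = SimulationTruth(
        de_flags=de_flags,
        true_effects=pd.DataFrame(effects, index=genes, columns=study_ids),
    )
    return studies, truth


def generate_tissue_atlas(
    n_genes: int,
    tissues: list[str],
    frac_specific: float = 0.5,
    seed: int = 0,
    dominance: float = 10.0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Gene x tissue expression atlas with one-tissue-dominant genes.

    Specific genes express ``dominance``-fold (or more) above every other
    tissue in one tissue; non-specific genes are near-uniform.  Truth
    records each specific gene's dominant tissue (None otherwise).
    """
    if len(tissues) < 2:
        raise ConfigurationError("atlas needs >=2 tissues")
    if not (0.0 <= frac_specific <= 1.0):
        raise ConfigurationError("frac_specific must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene_id")
    n_spec = int(round(frac_specific * n_genes))
    spec_idx = rng.choice(n_genes, size=n_spec, replace=False)
    base = rng.uniform(5.0, 15.0, size=(n_genes, len(tissues)))
    labels = np.full(n_genes, None, dtype=object)
    for gi in spec_idx:
        t = rng.integers(len(tissues))
        base[gi, t] = base[gi].max() * dominance * rng.uniform(1.0, 2.0)
        labels[gi] = tissues[t]
    atlas = pd.DataFrame(base, index=genes, columns=tissues)
    truth = SimulationTruth(specific_tissue=pd.Series(labels, index=genes, name="specific_tissue"))
    return atlas, truth


def generate_coexpression_data(
    n_samples: int,
    n_genes: int,
    n_modules: int,
    within_cor: float = 0.8,
    trait_cor: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, SimulationTruth]:
    """Latent-factor module-structured expression with a trait-linked module.

    Genes split evenly over ``n_modules`` latent eigengenes; gene g in
    module m is within_cor * E_m + sqrt(1 - within_cor^2) * noise.  Module
    1's eigengene carries correlation ``trait_cor`` with a balanced binary
    trait.  Returns (genes x samples expression, 0/1 trait, truth).
    """
    if n_modules < 1:
        raise ConfigurationError("n_modules must be >=1")
    if not (0 < within_cor < 1) or not (0 <= trait_cor < 1):
        raise ConfigurationError("correlations must lie in (0, 1)")
    if n_genes < n_modules:
        raise ConfigurationError("need at least one gene per module")
    rng = np.random.default_rng(seed)
    trait = np.zeros(n_samples, dtype=int)
    trait[: n_samples // 2] = 1
    rng.shuffle(trait)
    z_trait = (trait - trait.mean()) / trait.std()

    eig = rng.normal(size=(n_modules, n_samples))
    eig[0] = trait_cor * z_trait + np.sqrt(1.0 - trait_cor**2) * rng.normal(size=n_samples)

    labels = np.repeat(np.arange(1, n_modules + 1), int(np.ceil(n_genes / n_modules)))[:n_genes]
    noise = rng.normal(size=(n_genes, n_samples))
    expr = within_cor * eig[labels - 1] + np.sqrt(1.0 - within_cor**2) * noise

    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene_id")
    samples = pd.Index([f"s{j:03d}" for j in range(n_samples)], name="sample_id")
    truth = SimulationTruth(module_labels=pd.Series(labels, index=genes, name="module"))
    return (
        pd.DataFrame(expr, index=genes, columns=samples),
        pd.Series(trait, index=samples, name="trait"),
        truth,
    )


def generate_gene_sets(
    module_labels: pd.Series,
    n_sets: int = 50,
    enrichment_strength: float = 0.8,
    seed: int = 0,
    set_size: int = 20,
):
    """GMT-style gene sets with some sets planted inside modules.

    One set is planted per module (up to ``n_sets``): a planted set draws
    ``enrichment_strength`` of its members from its module and the rest
    uniformly; decoy sets draw uniformly from all genes.  Returns the
    collection plus a truth whose ``enriched_sets`` lists planted set ids.
    """
    from .enrich import GeneSetCollection

    if len(module_labels) == 0:
        raise ConfigurationError("module_labels must be non-empty")
    rng = np.random.default_rng(seed)
    all_genes = np.asarray(module_labels.index, dtype=object)
    modules = sorted(set(module_labels) - {0})
    sets = {}
    planted = []
    for si in range(n_sets):
        sid = f"SET{si:04d}"
        if si < len(modules):
            mod_genes = np.asarray(module_labels.index[module_labels == modules[si]], dtype=object)
            n_in = min(int(round(enrichment_strength * set_size)), mod_genes.size)
            inside = rng.choice(mod_genes, size=n_in, replace=False)
            pool = np.setdiff1d(all_genes, inside)
            outside = rng.choice(pool, size=set_size - n_in, replace=False)
            members = tuple(np.concatenate([inside, outside]))
            sets[sid] = (f"planted_module{modules[si]}", members)
            planted.append(sid)
        else:
            members = tuple(rng.choice(all_genes, size=min(set_size, all_genes.size), replace=False))
            sets[sid] = ("decoy", members)
    collection = GeneSetCollection(sets=sets, universe=frozenset(all_genes))
    truth = SimulationTruth(module_labels=module_labels, enriched_sets=planted)
    return collection, truth


def write_studies(studies: list[StudyCounts], outdir) -> dict:
    """Write per-study count TSVs plus a combined design TSV; returns paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"counts": {}, "design": str(outdir / "design.tsv")}
    designs = []
    for st in studies:
        p = outdir / f"counts_{st.study_id}.tsv"
        st.counts.to_csv(p, sep="\t")
        paths["counts"][st.study_id] = str(p)
        designs.append(st.design)
    pd.concat(designs).to_csv(paths["design"], sep="\t")
    return paths


def write_truth(truth: SimulationTruth, path) -> None:
    """Serialize the ground truth to JSON."""
    payload = {
        "de_flags": {k: bool(v) for k, v in truth.de_flags.items()},
        "true_effects": {
            c: truth.true_effects[c].round(6).to_dict() for c in truth.true_effects.columns
        },
        "specific_tissue": {k: v for k, v in truth.specific_tissue.items()},
        "module_labels": {k: int(v) for k, v in truth.module_labels.items()},
        "enriched_sets": list(truth.enriched_sets),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
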