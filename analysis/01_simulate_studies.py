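"""Generate the synthetic multi-study compendium used by all later steps.

Emulates a ~20-study case/control RNA-seq collection with very unequal arm
sizes (3-58 cases, 3-234 controls), NB counts, 10% DE genes at SMD 0.6
(balanced up/down) with mild between-study heterogeneity, plus a
six-tissue expression atlas with one-tissue-dominant genes.  Writes count
and design TSVs, the atlas and the ground truth under results/data/.
"""

from pathlib import Path

from lncmeta.simulate import (
    SimulationConfig,
    generate_multistudy_counts,
    generate_tissue_atlas,
    write_studies,
    write_truth,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 0


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    studies, truth = generate_multistudy_counts(cfg)
    write_studies(studies, OUT)
    write_truth(truth, OUT / "truth.json")
    atlas, atlas_truth = generate_tissue_atlas(
        cfg.n_genes, ["brain", "blood", "heart", "liver", "lung", "muscle"],
        frac_specific=0.3, seed=SEED + 1,
    )
    atlas.to_csv(OUT / "atlas.tsv", sep="\t")
    atlas_truth.specific_tissue.to_csv(OUT / "atlas_truth.tsv", sep="\t")
    sizes = [(len(s.case_samples), len(s.control_samples)) for s in studies]
    print(f"wrote {len(studies)} studies ({sum(a for a, _ in sizes)} cases, "
          f"{sum(b for _, b in sizes)} controls), {cfg.n_genes} genes -> {OUT}")
    print(f"planted DE genes: {int(truth.de_flags.sum())} "
          f"(SMD {cfg.delta}, tau2 {cfg.tau2}); atlas-specific genes: "
          f"{atlas_truth.specific_tissue.notna().sum()}")


if __name__ == "__main__":
    main()
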