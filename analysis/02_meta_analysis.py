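"""Heterogeneity test and meta-analysis on the whole compendium and the
brain/blood subgroups, plus the Venn overlap of the three DE sets.

Reads results/data/ (run 01 first); writes per-gene meta TSVs, the
overlap table, and prints the headline rates: heterogeneity flag rate,
DE counts and direction split, and DE recovery against the truth.
"""

import json
from pathlib import Path

import pandas as pd

from lncmeta.meta import MetaConfig, run_meta
from lncmeta.pipeline import de_overlap, load_studies

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"


def main() -> None:
    counts = sorted(DATA.glob("counts_*.tsv"))
    studies = load_studies(counts, DATA / "design.tsv")
    cfg = MetaConfig(seed=0)

    runs = {"whole": run_meta(studies, cfg)}
    for level in ("brain", "blood"):
        sub = [s for s in studies if (s.design["tissue_class"] == level).all()]
        runs[level] = run_meta(sub, cfg)

    truth = json.loads((DATA / "truth.json").read_text())
    de_true = {g for g, f in truth["de_flags"].items() if f}
    for name, res in runs.items():
        res.to_csv(ROOT / f"meta_{name}.tsv", sep="\t")
        het = ((res["I2"] > 50) & (res["p_Q"] < 0.01)).mean()
        de = res.index[res["de_call"]]
        tp = len(set(de) & de_true)
        up = (res.loc[de, "direction"] == "up").sum()
        print(f"[{name}] heterogeneity flag rate {100 * het:.2f}%; "
              f"{len(de)} DE genes ({up} up / {len(de) - up} down); "
              f"{tp}/{len(de_true)} planted DE recovered")

    sets = {n: list(r.index[r["de_call"]]) for n, r in runs.items()}
    overlap = de_overlap(sets)
    overlap.to_csv(ROOT / "de_overlap.tsv", sep="\t", index=False)
    both = overlap.set_index("region")
    for sub in ("brain", "blood"):
        shared = len(set(sets["whole"]) & set(sets[sub]))
        pct = 100 * shared / len(sets["whole"]) if sets["whole"] else 0.0
        print(f"{pct:.2f}% of whole-sample DE genes also found in {sub}")
    print(f"overlap table -> {ROOT / 'de_overlap.tsv'} ({len(both)} Venn regions)")


if __name__ == "__main__":
    main()
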