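#!/usr/bin/env python
"""Cohort statistics along the metastatic path.

Aggregates labeled pixels to one value per (patient, site, category,
channel) with the 150-pixel annotation filter and the 5-TMA combination
filter, runs the two-tailed paired t-test loop over every channel and
combination pair with BH adjustment, profiles the Hex6HexNAc2 trend per
patient, and writes the class-ordered heatmap table.  Also runs the
pixel-level unit-variance PCA contrasting bone and liver metastases.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from glycotma import cohort_stats as cs
from glycotma import glycan_chem as gc
from glycotma import pipeline as pl
from glycotma import synthetic_cohort as sc

SEED = 1
ROOT = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    bundle = sc.generate_cohort(sc.CohortConfig(seed=SEED), geometry=False)
    attrs = pd.read_csv(SCRATCH / "attrs.tsv", sep="\t")
    cfg = cs.StatsConfig()

    agg, report = cs.aggregate(attrs, bundle.dataset, cfg)
    print(f"aggregated to {len(agg)} (patient, site, category, channel) "
          f"means; {report['n_regions_removed']} regions below "
          f"{cfg.min_pixels} pixels removed, {report['n_regions_kept']} kept")

    retained = cs.retain_combinations(agg, cfg)
    n_before = agg.groupby(["tissue_site", "category"]).ngroups
    n_after = retained.groupby(["tissue_site", "category"]).ngroups
    print(f"{n_after} of {n_before} (site, category) combinations present "
          f"in >= {cfg.min_tmas} TMAs")

    comparisons = cs.paired_tests(agg, cfg)
    sig = comparisons[comparisons["p_adj"] < cfg.alpha]
    print(f"{len(comparisons)} paired tests; {len(sig)} significant at "
          f"adjusted p < {cfg.alpha} covering "
          f"{sig['channel'].nunique()} of {bundle.dataset.mz.size} channels")

    ann = gc.annotate_peak_list(bundle.dataset.mz)
    annotated = comparisons.merge(ann.rename(columns={"mz": "channel"}),
                                  on="channel", how="left")
    annotated.to_csv(SCRATCH / "comparisons.tsv", sep="\t", index=False)
    annotated[annotated["p_adj"] < cfg.alpha].to_csv(
        ROOT / "significant_comparisons.tsv", sep="\t", index=False)
    agg.to_csv(SCRATCH / "aggregate.tsv", sep="\t", index=False)

    man6 = gc.sodiated_mz(gc.parse_composition("Hex6HexNAc2"))
    profile, fraction = cs.trend_profile(agg, man6)
    n = int(profile["consistent"].dropna().sum())
    total = int(profile["consistent"].notna().sum())
    print(f"Hex6HexNAc2 (m/z {man6:.1f}) metastatic-path trend: "
          f"{n}/{total} patients consistent ({100 * fraction:.0f}%)")
    profile.to_csv(ROOT / "trend_hex6hexnac2.tsv", sep="\t")

    tables = pl.report_tables(agg, comparisons, ann)
    tables["heatmap"].to_csv(ROOT / "heatmap_table.tsv", sep="\t",
                             index=False)
    pl.save_heatmap_figure(tables["heatmap"], SCRATCH / "heatmap.png")

    # bone vs liver metastasis separation of cancer-bearing pixels
    cancer = attrs["category"].isin(cs.CANCER_CATEGORIES)
    pca = cs.pca_pixels(
        bundle.dataset,
        attrs.where(cancer),
        groups=["bone", "liver"])
    print(f"bone/liver PCA: PC1 {100 * pca.explained_variance[0]:.1f}% and "
          f"PC2 {100 * pca.explained_variance[1]:.1f}% of variance; "
          f"95% ellipses for {sorted(pca.ellipses)}")
    print(f"wrote comparisons, aggregate, trend and heatmap tables to {ROOT}")


if __name__ == "__main__":
    main()
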