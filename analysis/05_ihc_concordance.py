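#!/usr/bin/env python
"""MSI-IHC concordance over dichotomized per-patient deltas.

For every channel, the per-patient metastasis-minus-primary difference
(cancer-bearing annotations only) is dichotomized at zero and compared
with each marker's binary profile by the exact two-sided binomial test,
BH-adjusted across channels per marker.  Scores the ranking of the
truth-coupled channels.
"""

from pathlib import Path

import pandas as pd

from glycotma import ihc_concordance as ihc
from glycotma import synthetic_cohort as sc

SEED = 1
ROOT = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    markers = ihc.read_marker_table(ROOT / "cohort" / "markers.tsv")
    agg = pd.read_csv(SCRATCH / "aggregate.tsv", sep="\t")
    table = ihc.concordance_table(agg, markers)
    table.to_csv(ROOT / "concordance.tsv", sep="\t", index=False)

    for marker, block in table.groupby("marker"):
        best = block.nsmallest(3, "p_adj")
        print(f"{marker}: {int((block['p_adj'] < 0.05).sum())} of "
              f"{len(block)} channels concordant at adjusted p < 0.05; "
              f"best channels "
              f"{[f'{m:.1f}' for m in best['channel']]} "
              f"(disagreements {best['n_disagreements'].tolist()})")

    truth = sc.SyntheticTruth.from_json(ROOT / "cohort" / "truth.json")
    rec = sc.score_recovery(
        {"cohort_id": truth.cohort_id, "concordance": table}, truth)
    print("truth-coupled channels rank lowest per marker:",
          rec["coupled_channels_rank_lowest"])
    print(f"wrote concordance table to {ROOT / 'concordance.tsv'}")


if __name__ == "__main__":
    main()
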