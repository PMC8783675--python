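#!/usr/bin/env python
"""Generate the default 17-patient synthetic TMA cohort.

Writes annotations, fiducials, the IHC-style marker table and the
ground truth under results/cohort/, and prints the cohort dimensions.
The channel-mode pixel matrix is regenerated on demand by the later
scripts (deterministic for the same seed) instead of being written to
disk, which keeps the results directory small.
"""

from pathlib import Path

from glycotma import annotation_registry as ar
from glycotma import synthetic_cohort as sc

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    cfg = sc.CohortConfig(seed=SEED)
    bundle = sc.generate_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    # the polygon file is several MB: large intermediates go to scratch/
    ar.write_annotations(bundle.annotations, SCRATCH / "regions.geojson")
    bundle.fiducials.to_csv(OUT / "fiducials.tsv", sep="\t", index=False)
    bundle.markers.to_csv(OUT / "markers.tsv", sep="\t", index=False)
    bundle.truth.to_json(OUT / "truth.json")

    n_cores = bundle.attrs.loc[
        bundle.attrs["category"].isin(["cancer", "normal"]),
        "region_id"].nunique()
    print(f"cohort {bundle.truth.cohort_id}:")
    print(f"  {cfg.n_patients} patients, {len(cfg.sites)} tissue sites each")
    print(f"  {n_cores} cores, {len(bundle.annotations)} annotation regions")
    print(f"  {bundle.dataset.n_pixels} pixels x {bundle.dataset.mz.size} "
          f"m/z channels (50 um pitch)")
    print(f"  trend-consistent patients (truth): "
          f"{int(bundle.truth.patients['consistent'].sum())}/{cfg.n_patients}")
    print(f"wrote fiducials, markers and truth to {OUT}; "
          f"annotation polygons to {SCRATCH / 'regions.geojson'}")


if __name__ == "__main__":
    main()
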