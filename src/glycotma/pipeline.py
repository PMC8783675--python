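"""Pipeline orchestration: simulate -> preprocess -> label -> stats ->
concordance -> report as a single configured, seeded, logged run.

A run is described by a RunConfig (usually loaded from YAML): stage
toggles, per-stage settings, paths and one global seed.  Each enabled
stage logs the counts at every filter (pixels labeled, annotations
dropped by the minimum-pixel filter, combinations dropped by the
minimum-TMA filter, tests performed, significant results), and a
RunManifest with per-file checksums is written even when a stage fails.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from glycotma import __version__
from glycotma import annotation_registry as ar
from glycotma import cohort_stats as cs
from glycotma import glycan_chem as gc
from glycotma import ihc_concordance as ihc
from glycotma import synthetic_cohort as sc

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run", "report_tables"]

STAGES = ("simulate", "label", "stats", "concordance", "report")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    outdir: str = "glycotma_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    cohort: sc.CohortConfig = field(default_factory=sc.CohortConfig)
    stats: cs.StatsConfig = field(default_factory=cs.StatsConfig)
    match: gc.MatchConfig = field(default_factory=gc.MatchConfig)
    trend_channel: str = "Hex6HexNAc2"
    write_pixel_table: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = {}
        if "cohort" in doc:
            c = dict(doc.pop("cohort"))
            for k in ("distant_sites", "bone_like_sites",
                      "cores_per_tumor_site", "ihc_couplings"):
                if k in c:
                    c[k] = tuple(tuple(x) if isinstance(x, list) else x
                                 for x in c[k]) if k == "ihc_couplings" \
                        else tuple(c[k])
            kwargs["cohort"] = sc.CohortConfig(**c)
        if "stats" in doc:
            kwargs["stats"] = cs.StatsConfig(**doc.pop("stats"))
        if "match" in doc:
            m = dict(doc.pop("match"))
            for k in ("hex_bounds", "hexnac_bounds", "dhex_bounds",
                      "neuac_bounds"):
                if k in m:
                    m[k] = tuple(m[k])
            kwargs["match"] = gc.MatchConfig(**m)
        if "stages" in doc:
            doc["stages"] = tuple(doc["stages"])
        kwargs.update(doc)
        return cls(**kwargs)


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    counts: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    completed_stages: list = field(default_factory=list)
    failed_stage: str | None = None
    error: str | None = None

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True,
                      default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in order.

    Any stage failure aborts with a diagnostic naming the stage; the
    (partial) manifest is written regardless.  Rerunning with the same
    config reproduces identical checksums.
    """
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__,
                           config_hash=_config_hash(config),
                           seed=config.seed)
    manifest_path = outdir / "manifest.json"

    state: dict = {}
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            logger.info("stage %s: starting", stage)
            _STAGE_FN[stage](config, state, manifest, outdir)
            manifest.completed_stages.append(stage)
    except Exception as e:  # noqa: BLE001 - manifest must record the stage
        manifest.failed_stage = stage
        manifest.error = str(e)
        manifest.write(manifest_path)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    for p in sorted(outdir.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest.checksums[p.name] = _sha256(p)
    manifest.write(manifest_path)
    return manifest


def _stage_simulate(config, state, manifest, outdir):
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    bundle = sc.generate_cohort(cohort_cfg)
    state["bundle"] = bundle
    manifest.counts["n_pixels"] = bundle.dataset.n_pixels
    manifest.counts["n_annotations"] = len(bundle.annotations)
    manifest.counts["n_channels"] = bundle.dataset.mz.size
    ar.write_annotations(bundle.annotations, outdir / "regions.geojson")
    bundle.fiducials.to_csv(outdir / "fiducials.tsv", sep="\t", index=False)
    bundle.markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)
    bundle.truth.to_json(outdir / "truth.json")
    if config.write_pixel_table:
        sc.write_cohort(bundle, outdir)


def _stage_label(config, state, manifest, outdir):
    bundle = state["bundle"]
    slide, grid = (bundle.fiducials[["slide_x_um", "slide_y_um"]].to_numpy(),
                   bundle.fiducials[["grid_x", "grid_y"]].to_numpy())
    transform, residuals = ar.fit_affine(slide, grid)
    attrs = ar.assign_pixels(bundle.dataset, bundle.annotations, transform)
    attrs = ar.pool_bone_sites(attrs)
    state["attrs"] = attrs
    manifest.counts["n_pixels_labeled"] = int(attrs["region_id"].notna().sum())
    manifest.counts["n_pixels_unlabeled"] = int(attrs["region_id"].isna().sum())
    manifest.counts["coreg_max_residual"] = float(residuals.max())


def _stage_stats(config, state, manifest, outdir):
    bundle = state["bundle"]
    attrs = state.get("attrs")
    if attrs is None:  # label stage skipped: use ground-truth labels
        attrs = ar.pool_bone_sites(bundle.attrs)
        state["attrs"] = attrs
    agg, agg_report = cs.aggregate(attrs, bundle.dataset, config.stats)
    retained = cs.retain_combinations(agg, config.stats)
    comparisons = cs.paired_tests(agg, config.stats)
    state["agg"] = agg
    state["comparisons"] = comparisons

    n_combos = agg.groupby(["tissue_site", "category"]).ngroups
    n_retained = retained.groupby(["tissue_site", "category"]).ngroups
    manifest.counts["n_regions_removed_by_pixel_filter"] = (
        agg_report["n_regions_removed"])
    manifest.counts["n_combinations_dropped_by_tma_filter"] = (
        n_combos - n_retained)
    manifest.counts["n_tests"] = len(comparisons)
    manifest.counts["n_significant"] = int(
        (comparisons["p_adj"] < config.stats.alpha).sum())
    manifest.counts["n_significant_channels"] = int(
        comparisons.loc[comparisons["p_adj"] < config.stats.alpha,
                        "channel"].nunique())
    agg.to_csv(outdir / "aggregate.tsv", sep="\t", index=False)
    ann = gc.annotate_peak_list(bundle.dataset.mz, config.match)
    merged = comparisons.merge(
        ann.rename(columns={"mz": "channel"}), on="channel", how="left")
    merged.to_csv(outdir / "comparisons.tsv", sep="\t", index=False)
    state["channel_annotations"] = ann


def _stage_concordance(config, state, manifest, outdir):
    bundle = state["bundle"]
    conc = ihc.concordance_table(state["agg"], bundle.markers)
    state["concordance"] = conc
    manifest.counts["n_concordance_tests"] = len(conc)
    manifest.counts["n_concordant_significant"] = int(
        (conc["p_adj"] < config.stats.alpha).sum())
    conc.to_csv(outdir / "concordance.tsv", sep="\t", index=False)


def _stage_report(config, state, manifest, outdir):
    tables = report_tables(
        state["agg"], state.get("comparisons"),
        state.get("channel_annotations"), trend_channel=config.trend_channel)
    for name, tab in tables.items():
        tab.to_csv(outdir / f"report_{name}.tsv", sep="\t",
                   index=name == "trend_profile")
    flags = tables["trend_profile"]["consistent"].dropna()
    manifest.counts["n_trend_consistent"] = int(flags.sum())
    manifest.counts["n_trend_patients"] = int(len(flags))


_STAGE_FN = {
    "simulate": _stage_simulate,
    "label": _stage_label,
    "stats": _stage_stats,
    "concordance": _stage_concordance,
    "report": _stage_report,
}


def report_tables(
    agg: pd.DataFrame,
    comparisons: pd.DataFrame | None = None,
    channel_annotations: pd.DataFrame | None = None,
    trend_channel: str = "Hex6HexNAc2",
) -> dict[str, pd.DataFrame]:
    """Report bundle: class-ordered heatmap table, per-patient trend table
    for the named glycan, and the significant-comparison summary."""
    if agg.empty:
        logger.warning("report_tables: empty aggregate, empty report")
        return {"heatmap": pd.DataFrame(),
                "trend_profile": pd.DataFrame(columns=["consistent"]),
                "significant": pd.DataFrame()}
    tables = {"heatmap": cs.heatmap_table(agg, channel_annotations)}

    mz = gc.sodiated_mz(gc.parse_composition(trend_channel))
    channels = np.asarray(sorted(agg["channel"].unique()), float)
    nearest = channels[np.argmin(np.abs(channels - mz))]
    profile, fraction = cs.trend_profile(agg, nearest)
    profile.attrs["channel"] = nearest
    profile.attrs["consistency_fraction"] = fraction
    tables["trend_profile"] = profile

    if comparisons is not None and len(comparisons):
        sig = comparisons[comparisons["p_adj"] < 0.05]
        tables["significant"] = sig.reset_index(drop=True)
    else:
        tables["significant"] = pd.DataFrame()
    return tables


def save_heatmap_figure(heatmap: pd.DataFrame, path) -> None:
    """Render the heatmap table (log-scaled means, channels grouped by
    glycan class) to PNG/SVG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = heatmap.pivot_table(index="channel",
                                columns=["tissue_site", "category"],
                                values="log_mean", sort=False)
    fig, ax = plt.subplots(figsize=(max(6, 0.35 * pivot.shape[1]),
                                    max(4, 0.18 * pivot.shape[0])))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_yticks(range(pivot.shape[0]))
    ax.set_yticklabels([f"{c:.1f}" for c in pivot.index], fontsize=6)
    ax.set_xticks(range(pivot.shape[1]))
    ax.set_xticklabels([f"{s}\n{c}" for s, c in pivot.columns],
                       fontsize=6, rotation=90)
    fig.colorbar(im, ax=ax, label="log10 mean intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
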