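"""Cohort-level spatial statistics over annotated TMA pixels.

The analysis aggregates pixel intensities to one value per
(TMA/patient, tissue site, histology category, channel), applying two
coverage filters — annotations with fewer than 150 pixels are dropped,
and (site, category) combinations present in fewer than 5 TMAs are
discarded — then runs a two-tailed paired t test per m/z channel for
every unordered pair of retained combinations, pairing values within
patients to cancel interindividual baselines.  P values are adjusted by
the Benjamini-Hochberg step-up procedure, by default within each
combination pair across channels.

Also provided: unit-variance PCA of pixel spectra with 95% confidence
ellipses per group, and per-patient trend profiles of a channel along
the metastatic path with a strict-increase consistency rule.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from glycotma.msi_preprocess import MSIDataset

logger = logging.getLogger(__name__)

__all__ = [
    "StatsConfig",
    "PCAResult",
    "aggregate",
    "retain_combinations",
    "paired_tests",
    "paired_t",
    "bh_adjust",
    "pca_pixels",
    "trend_profile",
    "summarize_consistency",
    "heatmap_table",
]

#: Cancer-bearing histology categories used for tumor-content analyses.
CANCER_CATEGORIES = ("cancer", "cancer_mixed_cas")

#: Featured contrasts from the study design (site, category) pairs.
FEATURED_CONTRASTS = [
    (("normal_breast", "normal"), ("primary_tumor", "cancer")),
    (("primary_tumor", "cancer"), ("bone", "cancer")),
    (("primary_tumor", "cancer"), ("lung", "cancer")),
    (("primary_tumor", "cancer"), ("liver", "cancer")),
    (("bone", "cancer"), ("liver", "cancer")),
]


@dataclass(frozen=True)
class StatsConfig:
    """Filters and thresholds for the statistical loop.

    min_pixels:  minimum pixels (spectra) per annotation region (default 150).
    min_tmas:    minimum distinct TMAs per (site, category) combination and
                 minimum paired observations per test (default 5).
    alpha:       significance level on BH-adjusted p (default 0.05).
    bh_family:   'per_pair' adjusts across channels within one combination
                 pair; 'global' adjusts across all tests at once.
    """

    min_pixels: int = 150
    min_tmas: int = 5
    alpha: float = 0.05
    bh_family: str = "per_pair"

    def __post_init__(self) -> None:
        if self.min_pixels <= 0 or self.min_tmas <= 0 or self.alpha <= 0:
            raise ValueError("thresholds must be positive")
        if self.bh_family not in ("per_pair", "global"):
            raise ValueError("bh_family must be 'per_pair' or 'global'")


def aggregate(
    attrs: pd.DataFrame,
    channels: MSIDataset,
    cfg: StatsConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Mean normalized intensity per (tma_id, tissue_site, category, channel).

    Annotation regions with fewer than cfg.min_pixels labeled pixels are
    removed before averaging; the surviving regions of a combination are
    pooled with pixel weighting (i.e. a plain mean over their union of
    pixels).  Returns (aggregate table, report dict with removal counts).
    """
    cfg = cfg or StatsConfig()
    if len(attrs) != channels.n_pixels:
        raise ValueError("attribute table and channel matrix disagree on pixels")
    labeled = attrs["region_id"].notna().to_numpy()
    if not labeled.any():
        logger.warning("aggregate: no labeled pixels")
        return (
            pd.DataFrame(columns=["tma_id", "tissue_site", "category",
                                  "channel", "mean_intensity", "n_pixels"]),
            {"n_regions_removed": 0, "n_regions_kept": 0},
        )

    lab = attrs.loc[labeled, ["tma_id", "tissue_site", "category", "region_id"]]
    inten = channels.intensities[labeled]

    region_sizes = lab.groupby("region_id").size()
    small = set(region_sizes[region_sizes < cfg.min_pixels].index)
    keep = ~lab["region_id"].isin(small).to_numpy()
    report = {
        "n_regions_removed": len(small),
        "n_regions_kept": int(region_sizes.size - len(small)),
    }
    if small:
        logger.info("aggregate: removed %d region(s) with < %d pixels",
                    len(small), cfg.min_pixels)
    lab = lab.loc[keep]
    inten = inten[keep.nonzero()[0]] if keep.dtype == bool else inten[keep]

    df = pd.DataFrame(inten, columns=[f"__c{j}" for j in range(inten.shape[1])])
    df[["tma_id", "tissue_site", "category"]] = lab[
        ["tma_id", "tissue_site", "category"]].to_numpy()
    grouped = df.groupby(["tma_id", "tissue_site", "category"], sort=True)
    means = grouped.mean()
    sizes = grouped.size()

    long = means.reset_index().melt(
        id_vars=["tma_id", "tissue_site", "category"],
        var_name="__ch", value_name="mean_intensity")
    long["channel"] = long["__ch"].str.removeprefix("__c").astype(int)
    long["channel"] = channels.mz[long["channel"].to_numpy()]
    long = long.drop(columns="__ch")
    long = long.merge(sizes.rename("n_pixels").reset_index(),
                      on=["tma_id", "tissue_site", "category"])
    cols = ["tma_id", "tissue_site", "category", "channel",
            "mean_intensity", "n_pixels"]
    return long[cols].sort_values(cols[:4]).reset_index(drop=True), report


def retain_combinations(
    agg: pd.DataFrame, cfg: StatsConfig | None = None
) -> pd.DataFrame:
    """Keep only (tissue_site, category) combinations present in at least
    cfg.min_tmas distinct TMAs (boundary inclusive)."""
    cfg = cfg or StatsConfig()
    if agg.empty:
        return agg
    counts = agg.groupby(["tissue_site", "category"])["tma_id"].nunique()
    good = counts[counts >= cfg.min_tmas].index
    idx = pd.MultiIndex.from_frame(agg[["tissue_site", "category"]])
    return agg[idx.isin(good)].reset_index(drop=True)


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Two-tailed paired t test; returns (t, df, p).

    If the paired differences have zero variance: p = 1 with t = 0 when
    all differences are exactly zero (no evidence), otherwise the
    statistic is infinite and p = 0.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, n - 1, 1.0
        logger.warning("paired_t: zero variance with nonzero differences")
        return float(np.sign(d.mean()) * np.inf), n - 1, 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order.

    adjusted[i] = min over ranks j >= rank(i) of m * p_(j) / j, capped at 1.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def paired_tests(
    agg: pd.DataFrame, cfg: StatsConfig | None = None
) -> pd.DataFrame:
    """Paired t tests for every channel and every unordered pair of
    retained (site, category) combinations.

    For each pair, differences are taken within TMAs containing both
    members; pairs with fewer than cfg.min_tmas common TMAs are skipped.
    BH adjustment is applied across channels within each pair (default)
    or globally.  Direction is the sign of the mean paired difference
    (combo_b minus combo_a).
    """
    cfg = cfg or StatsConfig()
    agg = retain_combinations(agg, cfg)
    if agg.empty:
        return pd.DataFrame(columns=[
            "site_a", "cat_a", "site_b", "cat_b", "channel", "n_pairs",
            "t", "df", "p", "p_adj", "direction"])

    wide = agg.pivot_table(index=["tissue_site", "category", "tma_id"],
                           columns="channel", values="mean_intensity")
    channels = wide.columns.to_numpy()
    combos = sorted(set(map(tuple, agg[["tissue_site", "category"]]
                            .drop_duplicates().to_numpy())))
    rows = []
    for combo_a, combo_b in itertools.combinations(combos, 2):
        block_a = wide.loc[combo_a]
        block_b = wide.loc[combo_b]
        common = block_a.index.intersection(block_b.index)
        if len(common) < cfg.min_tmas:
            continue
        A = block_a.loc[common].to_numpy()
        B = block_b.loc[common].to_numpy()
        pvals, tstats = [], []
        for j in range(len(channels)):
            t, df, p = paired_t(B[:, j], A[:, j])
            tstats.append(t)
            pvals.append(p)
        diff_mean = (B - A).mean(axis=0)
        block = pd.DataFrame({
            "site_a": combo_a[0], "cat_a": combo_a[1],
            "site_b": combo_b[0], "cat_b": combo_b[1],
            "channel": channels,
            "n_pairs": len(common),
            "t": tstats,
            "df": len(common) - 1,
            "p": pvals,
            "direction": np.sign(diff_mean).astype(int),
        })
        if cfg.bh_family == "per_pair":
            block["p_adj"] = bh_adjust(block["p"].to_numpy())
        rows.append(block)
    if not rows:
        return pd.DataFrame(columns=[
            "site_a", "cat_a", "site_b", "cat_b", "channel", "n_pairs",
            "t", "df", "p", "p_adj", "direction"])
    out = pd.concat(rows, ignore_index=True)
    if cfg.bh_family == "global":
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    cols = ["site_a", "cat_a", "site_b", "cat_b", "channel", "n_pairs",
            "t", "df", "p", "p_adj", "direction"]
    return out[cols]


# --- PCA ---------------------------------------------------------------------

@dataclass
class PCAResult:
    """Unit-variance PCA of pixel spectra.

    scores:             (n_pixels, n_components) pixel scores.
    loadings:           (n_channels_kept, n_components), orthonormal columns.
    explained_variance: fractions in [0, 1], non-increasing.
    channels:           channels kept (zero-variance channels dropped).
    ellipses:           per group: center, half-axis lengths and angle of
                        the 95% confidence ellipse in the PC1/PC2 plane.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    channels: np.ndarray
    groups: pd.Series
    ellipses: dict


def _confidence_ellipse(points: np.ndarray, level: float = 0.95) -> dict:
    center = points.mean(axis=0)
    cov = np.cov(points, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    q = stats.chi2.ppf(level, df=2)
    half_axes = np.sqrt(np.maximum(evals, 0) * q)
    angle = float(np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1])))
    return {"center": center, "half_axes": half_axes[::-1], "angle": angle}


def pca_pixels(
    channels: MSIDataset,
    attrs: pd.DataFrame | None = None,
    groups: list[str] | None = None,
    group_col: str = "tissue_site",
    n_components: int | None = None,
) -> PCAResult:
    """PCA of per-pixel channel intensities, unit-variance scaled.

    Channels are centered and scaled to unit variance (zero-variance
    channels dropped with a warning), so the decomposition acts on the
    correlation structure.  If attrs/groups are given, pixels are
    restricted to those groups and a 95% confidence ellipse (chi-square
    quantile, 2 df) is fitted to each group's PC1/PC2 scores.
    """
    from sklearn.decomposition import PCA

    X = channels.intensities
    group_labels = None
    if attrs is not None and groups is not None:
        mask = attrs[group_col].isin(groups).to_numpy()
        X = X[mask]
        group_labels = attrs.loc[mask, group_col].reset_index(drop=True)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 3 pixels and 2 channels")

    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("pca_pixels: dropped %d zero-variance channel(s)",
                       int((~keep).sum()))
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    ellipses = {}
    if group_labels is not None and scores.shape[1] >= 2:
        for g in group_labels.unique():
            pts = scores[(group_labels == g).to_numpy(), :2]
            if len(pts) >= 3:
                ellipses[g] = _confidence_ellipse(pts)
    return PCAResult(
        scores=scores,
        loadings=pca.components_.T,
        explained_variance=pca.explained_variance_ratio_,
        channels=channels.mz[keep],
        groups=group_labels if group_labels is not None else pd.Series(dtype=object),
        ellipses=ellipses,
    )


# --- metastatic-path trend profiles -----------------------------------------

#: Default ordered metastatic path; lymph node is an intermediate stage.
DEFAULT_PATH = ("normal_breast", "primary_tumor", "lymph_node", "distant")

#: Sites treated as distant metastases when pooling (lymph node excluded:
#: the sentinel node shows levels comparable with the primary tumor).
NON_DISTANT_SITES = frozenset({"normal_breast", "primary_tumor", "lymph_node"})


def trend_profile(
    agg: pd.DataFrame,
    channel: float,
    path: tuple[str, ...] = DEFAULT_PATH,
) -> tuple[pd.DataFrame, float]:
    """Per-patient stage means of one channel along the metastatic path,
    restricted to cancer-bearing annotations, plus a consistency flag.

    The final path stage 'distant' pools all sites outside
    {normal_breast, primary_tumor, lymph_node} with pixel weighting.
    A patient is trend-consistent when the pooled distant-metastasis mean
    strictly exceeds the primary-tumor mean.  Patients lacking a primary
    tumor value are excluded from the cohort fraction (logged).

    Returns (per-patient table with one column per stage plus
    'consistent', cohort consistency fraction).
    """
    sub = agg[np.isclose(agg["channel"].astype(float), channel)]
    cancerish = sub["category"].isin(CANCER_CATEGORIES)
    normal = (sub["tissue_site"] == "normal_breast") & (sub["category"] == "normal")
    sub = sub[cancerish | normal].copy()

    def stage_of(site: str) -> str:
        return site if site in NON_DISTANT_SITES else "distant"

    sub["stage"] = sub["tissue_site"].map(stage_of)
    sub = sub[sub["stage"].isin(path)]
    weighted = sub.assign(w=sub["mean_intensity"] * sub["n_pixels"])
    g = weighted.groupby(["tma_id", "stage"])
    stage_means = (g["w"].sum() / g["n_pixels"].sum()).unstack("stage")
    stage_means = stage_means.reindex(columns=list(path))

    flags = []
    for tma, row in stage_means.iterrows():
        pt, met = row.get("primary_tumor"), row.get("distant")
        if pd.isna(pt) or pd.isna(met):
            flags.append(np.nan)
            logger.info("trend_profile: %s lacks PT or distant mean; excluded",
                        tma)
        else:
            flags.append(bool(met > pt))
    stage_means["consistent"] = flags
    valid = stage_means["consistent"].dropna()
    fraction = float(valid.sum() / len(valid)) if len(valid) else float("nan")
    return stage_means, fraction


def summarize_consistency(flags) -> tuple[int, int, float]:
    """Cohort consistency summary from per-patient boolean flags.

    Returns (n_consistent, n_total, percent consistent)."""
    flags = [bool(f) for f in flags]
    n = len(flags)
    k = sum(flags)
    return k, n, 100.0 * k / n if n else float("nan")


# --- reporting ---------------------------------------------------------------

def heatmap_table(
    agg: pd.DataFrame,
    channel_annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Log-scaled mean intensity per (site, category, channel) across TMAs,
    channels ordered by glycan class when annotations are provided."""
    tab = (agg.groupby(["tissue_site", "category", "channel"])
           ["mean_intensity"].mean().reset_index())
    tab["log_mean"] = np.log10(tab["mean_intensity"].clip(lower=1e-12))
    if channel_annotations is not None:
        ann = channel_annotations[["mz", "composition", "glycan_class"]].rename(
            columns={"mz": "channel"})
        tab = tab.merge(ann, on="channel", how="left")
        tab = tab.sort_values(["glycan_class", "channel",
                               "tissue_site", "category"])
    return tab.reset_index(drop=True)
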