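"""MSI-IHC concordance: binary-profile agreement between per-patient
glycan changes and marker changes.

For each patient, the average channel intensity is computed for the
primary tumor and for all metastases pooled together, restricted to the
cancer-bearing annotations (cancer, cancer mixed with cancer-associated
stroma).  The metastasis-minus-primary difference is dichotomized at
zero for both the glycan channel and the marker (e.g. EpCAM IHC score,
c-MYC FISH amplification); positions where the two binary profiles
disagree are counted and the count is tested against a symmetric
binomial null (probability 0.5) with an exact two-sided test.
Benjamini-Hochberg correction is applied across channels per marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from glycotma.cohort_stats import CANCER_CATEGORIES, bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "patient_deltas",
    "dichotomize",
    "binomial_concordance",
    "concordance_table",
    "read_marker_table",
]

#: Sites never counted as metastases when pooling.
NON_MET_SITES = frozenset({"normal_breast", "primary_tumor"})


def patient_deltas(agg: pd.DataFrame, channel: float) -> pd.Series:
    """Per-patient (pooled metastasis - primary tumor) mean difference
    for one channel, using cancer-bearing annotations only.

    Metastasis pooling is pixel-weighted over every site outside
    {normal_breast, primary_tumor} (the sentinel lymph node counts as a
    metastasis here).  Patients missing either side are excluded and
    logged.
    """
    sub = agg[np.isclose(agg["channel"].astype(float), channel)]
    sub = sub[sub["category"].isin(CANCER_CATEGORIES)]
    out = {}
    for tma, block in sub.groupby("tma_id"):
        pt = block[block["tissue_site"] == "primary_tumor"]
        met = block[~block["tissue_site"].isin(NON_MET_SITES)]
        if pt.empty or met.empty:
            logger.info("patient_deltas: %s lacks PT or metastasis values", tma)
            continue
        pt_mean = np.average(pt["mean_intensity"], weights=pt["n_pixels"])
        met_mean = np.average(met["mean_intensity"], weights=met["n_pixels"])
        out[tma] = met_mean - pt_mean
    return pd.Series(out, dtype=float).sort_index()


def dichotomize(deltas) -> np.ndarray:
    """Binary profile of differences with zero as the threshold:
    1 if delta > 0, else 0 (exact zeros map to 0)."""
    return (np.asarray(deltas, float) > 0).astype(int)


def binomial_concordance(
    glycan_bits, marker_bits, alternative: str = "two-sided"
) -> dict:
    """Exact binomial test of binary-profile disagreement.

    x = number of positions where the profiles disagree, tested against
    Binomial(n, 0.5).  Two-sided p doubles the smaller tail probability
    (capped at 1), which for the symmetric null equals summing both
    tails; one-sided alternatives ('less': fewer disagreements than
    chance, i.e. concordance; 'greater') are available.
    """
    a = np.asarray(glycan_bits, int)
    b = np.asarray(marker_bits, int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("bit vectors must be 1-D and of equal length")
    n = a.size
    if n == 0:
        raise ValueError("empty profiles")
    x = int(np.sum(a != b))
    lower = stats.binom.cdf(x, n, 0.5)
    upper = stats.binom.sf(x - 1, n, 0.5)
    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(lower, upper))
    elif alternative == "less":
        p = lower
    elif alternative == "greater":
        p = upper
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return {"n_patients": n, "n_disagreements": x, "p": float(p)}


def read_marker_table(path) -> pd.DataFrame:
    """Read a delimited marker table with columns
    patient_id, marker, pt_value, met_value."""
    df = pd.read_csv(path, sep="\t")
    need = {"patient_id", "marker", "pt_value", "met_value"}
    if not need.issubset(df.columns):
        raise ValueError(f"marker table must have columns {sorted(need)}")
    return df


def concordance_table(
    agg: pd.DataFrame,
    markers: pd.DataFrame,
    channels=None,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Concordance tests for every (channel, marker) pair.

    Only patients with both a marker record and MSI deltas enter a
    comparison.  BH adjustment runs across channels within each marker.
    Returns columns channel, marker, n_patients, n_disagreements, p, p_adj.
    """
    if channels is None:
        channels = sorted(agg["channel"].unique())
    rows = []
    deltas = {ch: patient_deltas(agg, ch) for ch in channels}
    for marker, mblock in markers.groupby("marker"):
        mdelta = pd.Series(
            (mblock["met_value"] - mblock["pt_value"]).to_numpy(),
            index=mblock["patient_id"].astype(str).to_numpy(),
        ).sort_index()
        marker_rows = []
        for ch in channels:
            g = deltas[ch]
            g.index = g.index.astype(str)
            common = g.index.intersection(mdelta.index)
            if len(common) == 0:
                logger.warning("concordance_table: no shared patients for "
                               "marker %s", marker)
                continue
            res = binomial_concordance(
                dichotomize(g.loc[common]),
                dichotomize(mdelta.loc[common]),
                alternative=alternative,
            )
            marker_rows.append({"channel": ch, "marker": marker, **res})
        if marker_rows:
            block = pd.DataFrame(marker_rows)
            block["p_adj"] = bh_adjust(block["p"].to_numpy())
            rows.append(block)
    if not rows:
        return pd.DataFrame(columns=["channel", "marker", "n_patients",
                                     "n_disagreements", "p", "p_adj"])
    return pd.concat(rows, ignore_index=True)
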