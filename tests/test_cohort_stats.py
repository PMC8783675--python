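"""Aggregation filters, paired-test loop, BH adjustment, PCA, trends."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from glycotma import cohort_stats as cs
from glycotma.msi_preprocess import MSIDataset

from conftest import make_agg


def pixel_table(region_sizes, intensity=1.0, tma="T1", site="liver",
                cat="cancer", n_channels=2, rng=None):
    """Build matching (attrs, dataset) with one row per pixel."""
    rows, vals = [], []
    for rid, n in region_sizes.items():
        for i in range(n):
            rows.append({"tma_id": tma, "x": len(rows), "y": 0,
                         "tissue_site": site, "category": cat,
                         "region_id": rid})
            if rng is None:
                vals.append([intensity] * n_channels)
            else:
                vals.append(rng.uniform(0, 2, n_channels))
    attrs = pd.DataFrame(rows)
    pixels = attrs[["tma_id", "x", "y"]].copy()
    mz = np.linspace(1000, 1001 + n_channels, n_channels)
    return attrs, MSIDataset(pixels, mz, np.array(vals, float))


class TestAggregate:
    def test_uniform_region_mean(self):
        attrs, d = pixel_table({"r1": 200}, intensity=3.5)
        agg, report = cs.aggregate(attrs, d)
        assert (agg["mean_intensity"] == 3.5).all()
        assert (agg["n_pixels"] == 200).all()
        assert report["n_regions_removed"] == 0

    def test_region_below_pixel_threshold_excluded(self):
        attrs, d = pixel_table({"r1": 149})
        agg, report = cs.aggregate(attrs, d)
        assert agg.empty and report["n_regions_removed"] == 1

    def test_boundary_region_of_exactly_150_pixels_kept(self):
        attrs, d = pixel_table({"r1": 150})
        agg, _ = cs.aggregate(attrs, d)
        assert not agg.empty

    def test_two_regions_pool_to_pixel_weighted_mean(self):
        rng = np.random.default_rng(0)
        attrs, d = pixel_table({"r1": 200, "r2": 600}, rng=rng)
        agg, _ = cs.aggregate(attrs, d)
        # brute-force oracle over the union of pixels
        for j, mz in enumerate(d.mz):
            expected = d.intensities[:, j].mean()
            got = agg.loc[np.isclose(agg["channel"], mz), "mean_intensity"]
            assert got.iloc[0] == pytest.approx(expected)

    def test_unlabeled_pixels_ignored(self):
        attrs, d = pixel_table({"r1": 200})
        attrs.loc[attrs.index[:50], "region_id"] = None
        attrs.loc[attrs.index[:50], "tissue_site"] = None
        agg, _ = cs.aggregate(attrs, d)
        assert (agg["n_pixels"] == 150).all()

    def test_no_labeled_pixels_gives_empty_table(self):
        attrs, d = pixel_table({"r1": 200})
        attrs["region_id"] = None
        agg, _ = cs.aggregate(attrs, d)
        assert agg.empty


class TestRetainCombinations:
    def base(self, n_tmas):
        return make_agg([(f"T{i}", "liver", "cancer", 1000.0, 1.0, 200)
                         for i in range(n_tmas)])

    def test_combination_in_four_tmas_dropped(self):
        assert cs.retain_combinations(self.base(4)).empty

    def test_combination_in_five_tmas_kept(self):
        assert len(cs.retain_combinations(self.base(5))) == 5

    def test_empty_input_empty_output(self):
        assert cs.retain_combinations(self.base(0)).empty


class TestPairedT:
    def test_identical_vectors_give_t_zero_p_one(self):
        t, df, p = cs.paired_t(np.ones(6), np.ones(6))
        assert (t, df, p) == (0.0, 5, 1.0)

    def test_matches_textbook_closed_form(self):
        a = np.array([2.1, 3.4, 1.9, 4.2, 3.3, 2.8])
        b = np.array([1.8, 3.1, 2.2, 3.0, 2.9, 2.1])
        t, df, p = cs.paired_t(a, b)
        d = a - b
        mean, sd = d.mean(), d.std(ddof=1)
        t_oracle = mean / (sd / math.sqrt(len(d)))
        p_oracle = 2 * (1 - sps.t.cdf(abs(t_oracle), len(d) - 1))
        assert t == pytest.approx(t_oracle, abs=1e-12)
        assert p == pytest.approx(p_oracle, abs=1e-12)
        # and the library cross-check
        ref = sps.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert cs.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_applied_step_up(self):
        got = cs.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_p_unchanged(self):
        assert np.allclose(cs.bh_adjust([0.2] * 7), 0.2)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 30)
        assert (cs.bh_adjust(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cs.bh_adjust([0.5, 1.2])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1,
                      max_size=12))
    def test_matches_definition_oracle_and_statsmodels(self, p):
        got = cs.bh_adjust(p)
        # brute-force step-up definition: adj_i = min_{j: p_j >= p_i}
        # over ranks of m*p_(j)/j, with monotonicity enforced from above
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        adj_sorted = [min(m * p[order[j]] / (j + 1) for j in range(k, m))
                      for k in range(m)]
        oracle = np.empty(m)
        oracle[order] = np.minimum(adj_sorted, 1.0)
        assert np.allclose(got, oracle, atol=1e-12)
        sm = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(got, sm, atol=1e-12)


class TestPairedTestsLoop:
    def toy_agg(self, shift=0.0, n_tmas=6):
        rows = []
        rng = np.random.default_rng(1)
        for i in range(n_tmas):
            base = rng.uniform(1, 2)
            for ch in (1000.0, 1200.0):
                rows.append((f"T{i}", "primary_tumor", "cancer", ch,
                             base, 200))
                rows.append((f"T{i}", "liver", "cancer", ch,
                             base + (shift if ch == 1000.0 else 0.0)
                             + rng.normal(0, 0.01), 200))
        return make_agg(rows)

    def test_identical_combos_give_p_one(self):
        agg = self.toy_agg(shift=0.0)
        agg.loc[agg["tissue_site"] == "liver", "mean_intensity"] = \
            agg.loc[agg["tissue_site"] == "primary_tumor",
                    "mean_intensity"].to_numpy()
        res = cs.paired_tests(agg)
        assert (res["t"] == 0).all() and (res["p"] == 1).all()

    def test_planted_shift_detected_with_direction(self):
        res = cs.paired_tests(self.toy_agg(shift=0.5))
        hit = res[np.isclose(res["channel"], 1000.0)].iloc[0]
        null = res[np.isclose(res["channel"], 1200.0)].iloc[0]
        assert hit["p_adj"] < 0.05 < null["p_adj"]
        # liver sorts before primary_tumor: direction = sign(PT - liver)
        assert hit["direction"] == -1

    def test_pairs_below_min_tma_threshold_skipped(self):
        res = cs.paired_tests(self.toy_agg(n_tmas=4))
        assert res.empty

    def test_t_statistics_invariant_under_row_permutation(self):
        agg = self.toy_agg(shift=0.3)
        rng = np.random.default_rng(2)
        shuffled = agg.sample(frac=1, random_state=3).reset_index(drop=True)
        r1 = cs.paired_tests(agg).sort_values("channel").reset_index(drop=True)
        r2 = cs.paired_tests(shuffled).sort_values("channel").reset_index(
            drop=True)
        assert np.allclose(r1["t"], r2["t"])

    def test_breaking_patient_pairing_reduces_mean_t(self, planted_agg,
                                                     planted_cohort):
        trend_mz = set(planted_cohort.truth.channels.loc[
            planted_cohort.truth.channels["role"] == "trend", "mz"])
        sub = planted_agg[
            planted_agg["tissue_site"].isin(["primary_tumor", "liver"])
            & (planted_agg["category"] == "cancer")].copy()
        paired = cs.paired_tests(sub)
        # shuffle the patient matching on the liver side
        rng = np.random.default_rng(0)
        broken = sub.copy()
        liver = broken["tissue_site"] == "liver"
        tmas = broken.loc[liver, "tma_id"].unique()
        mapping = dict(zip(tmas, rng.permutation(tmas)))
        broken.loc[liver, "tma_id"] = broken.loc[liver, "tma_id"].map(mapping)
        unpaired = cs.paired_tests(broken)
        sel = paired["channel"].isin(trend_mz)
        assert (paired.loc[sel, "t"].abs().mean()
                > unpaired.loc[sel, "t"].abs().mean())


class TestPCA:
    def dataset(self, X):
        pixels = pd.DataFrame({"tma_id": "T1", "x": np.arange(len(X)), "y": 0})
        return MSIDataset(pixels, np.arange(X.shape[1]) + 1000.0,
                          np.asarray(X, float))

    def test_perfectly_correlated_channels_load_on_single_component(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 1, 50)
        res = cs.pca_pixels(self.dataset(np.column_stack([v, 2 * v])))
        assert res.explained_variance[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_noise_spreads_variance_evenly(self):
        rng = np.random.default_rng(1)
        res = cs.pca_pixels(self.dataset(rng.normal(0, 1, (4000, 4))))
        assert res.explained_variance.max() < 0.30  # 1/4 within MC error

    def test_loadings_are_orthonormal_and_variance_monotone(self):
        rng = np.random.default_rng(2)
        res = cs.pca_pixels(self.dataset(rng.uniform(0, 1, (100, 5))))
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(5),
                           atol=1e-9)
        assert (np.diff(res.explained_variance) <= 1e-12).all()
        assert res.explained_variance.sum() <= 1 + 1e-9

    def test_zero_variance_channel_dropped(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.normal(size=30), np.full(30, 2.0),
                             rng.normal(size=30)])
        res = cs.pca_pixels(self.dataset(X))
        assert res.channels.size == 2

    def test_separated_groups_give_disjoint_ellipses(self):
        rng = np.random.default_rng(4)
        n = 200
        X = rng.normal(0, 0.3, (2 * n, 3))
        # correlated shift on two channels: under unit-variance scaling a
        # single-channel shift cannot dominate the decomposition
        X[n:, 0] += 8.0
        X[n:, 1] += 8.0
        d = self.dataset(X)
        attrs = pd.DataFrame({"tissue_site": ["bone"] * n + ["liver"] * n})
        res = cs.pca_pixels(d, attrs, groups=["bone", "liver"])
        e1, e2 = res.ellipses["bone"], res.ellipses["liver"]
        sep = e2["center"] - e1["center"]
        dist = np.linalg.norm(sep)
        u = sep / dist

        def extent(e):
            # support of the ellipse along u
            th = np.deg2rad(e["angle"])
            v1 = np.array([np.cos(th), np.sin(th)])
            v2 = np.array([-np.sin(th), np.cos(th)])
            a, b = e["half_axes"]
            return np.hypot(a * u @ v1, b * u @ v2)

        assert dist > extent(e1) + extent(e2)


class TestTrendProfile:
    def patient(self, tma, pt, met, normal=0.5, ln=None):
        rows = [(tma, "normal_breast", "normal", 1419.5, normal, 300),
                (tma, "primary_tumor", "cancer", 1419.5, pt, 300),
                (tma, "liver", "cancer", 1419.5, met, 300),
                (tma, "bone", "cancer_mixed_cas", 1419.5, met, 300)]
        if ln is not None:
            rows.append((tma, "lymph_node", "cancer", 1419.5, ln, 300))
        return rows

    def test_mets_above_pt_is_consistent(self):
        agg = make_agg(self.patient("T1", pt=1.0, met=1.4))
        profile, fraction = cs.trend_profile(agg, 1419.5)
        assert profile.loc["T1", "consistent"] and fraction == 1.0

    def test_all_stages_equal_is_inconsistent(self):
        agg = make_agg(self.patient("T1", pt=1.0, met=1.0))
        profile, fraction = cs.trend_profile(agg, 1419.5)
        assert not profile.loc["T1", "consistent"] and fraction == 0.0

    def test_lymph_node_excluded_from_distant_pool(self):
        # a huge lymph-node value must not rescue a flat distant trend
        agg = make_agg(self.patient("T1", pt=1.0, met=0.9, ln=5.0))
        profile, _ = cs.trend_profile(agg, 1419.5)
        assert not profile.loc["T1", "consistent"]
        assert profile.loc["T1", "lymph_node"] == pytest.approx(5.0)

    def test_patient_without_pt_excluded_from_fraction(self):
        rows = (self.patient("T1", pt=1.0, met=2.0)
                + [("T2", "liver", "cancer", 1419.5, 2.0, 300)])
        agg = make_agg(rows)
        profile, fraction = cs.trend_profile(agg, 1419.5)
        assert np.isnan(profile.loc["T2", "consistent"])
        assert fraction == 1.0

    def test_distant_pool_is_pixel_weighted(self):
        rows = [("T1", "primary_tumor", "cancer", 1419.5, 1.0, 300),
                ("T1", "liver", "cancer", 1419.5, 2.0, 100),
                ("T1", "lung", "cancer", 1419.5, 4.0, 300)]
        agg = make_agg(rows)
        profile, _ = cs.trend_profile(agg, 1419.5)
        assert profile.loc["T1", "distant"] == pytest.approx(
            (2.0 * 100 + 4.0 * 300) / 400)

    def test_non_cancer_categories_ignored(self):
        rows = (self.patient("T1", pt=1.0, met=2.0)
                + [("T1", "liver", "stroma", 1419.5, 50.0, 300)])
        profile, _ = cs.trend_profile(make_agg(rows), 1419.5)
        assert profile.loc["T1", "distant"] == pytest.approx(2.0)


def test_summarize_consistency_worked_fraction():
    flags = [True] * 12 + [False] * 5
    k, n, percent = cs.summarize_consistency(flags)
    assert (k, n) == (12, 17)
    assert percent == pytest.approx(100 * 12 / 17)


def test_heatmap_table_is_log_scaled_and_class_ordered(planted_agg):
    from glycotma import glycan_chem as gc
    ann = gc.annotate_peak_list(sorted(planted_agg["channel"].unique()))
    tab = cs.heatmap_table(planted_agg, ann)
    assert {"log_mean", "glycan_class"} <= set(tab.columns)
    one = tab.iloc[0]
    assert one["log_mean"] == pytest.approx(np.log10(one["mean_intensity"]))
    classes = tab["glycan_class"].tolist()
    assert classes == sorted(classes)
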