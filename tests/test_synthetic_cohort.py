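"""Synthetic cohort generator: determinism, planted structure, raw spectra."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from glycotma import annotation_registry as ar
from glycotma import cohort_stats as cs
from glycotma import msi_preprocess as mp
from glycotma import synthetic_cohort as sc


def small_cfg(**kw):
    defaults = dict(seed=3, n_patients=2, distant_sites=("bone", "liver"))
    defaults.update(kw)
    return sc.CohortConfig(**defaults)


class TestChannelRoster:
    def test_default_roster_shape_and_roles(self):
        tab = sc.default_channel_table()
        assert len(tab) == 42
        assert tab["role"].value_counts().to_dict() == {
            "null_glycan": 11, "unannotated": 17, "trend": 10, "bone_fuc": 4}
        assert {"Hex5HexNAc2", "Hex6HexNAc2", "Hex3dHex1HexNAc4",
                "Hex5HexNAc4", "Hex5dHex1HexNAc4"} <= set(tab["composition"])

    def test_channels_ascending_and_spaced(self):
        mz = sc.default_channel_table()["mz"].to_numpy()
        assert (np.diff(mz) >= 3.9).all()

    def test_unannotated_channels_match_nothing(self):
        from glycotma import glycan_chem as gc
        tab = sc.default_channel_table()
        for mz in tab.loc[tab["role"] == "unannotated", "mz"]:
            assert gc.match_mz(float(mz)) == []


class TestGenerateCohort:
    def test_identical_seed_gives_byte_identical_files(self, tmp_path):
        hashes = []
        for sub in ("a", "b"):
            bundle = sc.generate_cohort(small_cfg())
            paths = sc.write_cohort(bundle, tmp_path / sub)
            digest = {}
            for name, p in paths.items():
                digest[name] = hashlib.sha256(p.read_bytes()).hexdigest()
            hashes.append(digest)
        assert hashes[0] == hashes[1]

    def test_different_seeds_differ(self):
        a = sc.generate_cohort(small_cfg(seed=1), geometry=False)
        b = sc.generate_cohort(small_cfg(seed=2), geometry=False)
        assert not np.array_equal(a.dataset.intensities, b.dataset.intensities)

    def test_layout_counts(self):
        cfg = small_cfg()
        b = sc.generate_cohort(cfg, geometry=False)
        assert set(b.attrs["tissue_site"]) == set(cfg.sites)
        assert set(b.attrs["category"]) == set(sc.CATEGORY_ORDER)
        # ~615 pixels per 1.4 mm core at 50 um pitch; cores are identified
        # by one cancer (or normal) sector each
        n_cores = b.attrs.loc[
            b.attrs["category"].isin(["cancer", "normal"]),
            "region_id"].nunique()
        assert b.dataset.n_pixels / n_cores == pytest.approx(615, abs=30)

    def test_cores_per_tumor_site_average_near_4_5(self):
        b = sc.generate_cohort(sc.CohortConfig(seed=9, n_patients=6),
                               geometry=False)
        cores = b.attrs[b.attrs["category"] == "cancer"]  # one per core
        per_site = cores.groupby(["tma_id", "tissue_site"])[
            "region_id"].nunique()
        assert 4.2 <= per_site.mean() <= 4.8
        assert per_site.isin([4, 5]).all()

    def test_consistent_fraction_is_exact_ground_truth(self):
        b = sc.generate_cohort(sc.CohortConfig(seed=4), geometry=False)
        assert b.truth.patients["consistent"].sum() == 12

    def test_patient_baselines_have_configured_sd(self):
        cfg = sc.CohortConfig(seed=8, n_patients=40)
        b = sc.generate_cohort(cfg, geometry=False)
        sd = b.truth.patients["baseline"].std(ddof=1)
        assert sd == pytest.approx(cfg.sigma_patient, rel=0.35)

    def test_pixel_log_residuals_are_normal_with_configured_sd(self):
        from scipy import stats
        cfg = small_cfg()
        b = sc.generate_cohort(cfg, geometry=False)
        rid = b.attrs["region_id"].iloc[0]
        rows = (b.attrs["region_id"] == rid).to_numpy()
        logs = np.log(b.dataset.intensities[rows, 0])
        assert logs.std(ddof=1) == pytest.approx(cfg.sigma_pixel, rel=0.15)
        assert stats.normaltest(logs).pvalue > 0.01

    def test_planted_met_effect_magnitude_on_log_scale(self):
        # empirical log-scale mets-vs-PT shift on trend channels (cancer
        # annotations, trend-consistent cohort) within 20% of the plant
        effects = []
        for seed in range(3):
            cfg = sc.CohortConfig(seed=seed, consistent_fraction=1.0)
            b = sc.generate_cohort(cfg, geometry=False)
            agg, _ = cs.aggregate(ar.pool_bone_sites(b.attrs), b.dataset)
            trend_mz = b.truth.channels.loc[
                b.truth.channels["role"] == "trend", "mz"]
            sub = agg[(agg["category"] == "cancer")
                      & agg["channel"].isin(trend_mz)]
            wide = sub.pivot_table(index="tma_id", columns="tissue_site",
                                   values="mean_intensity")
            distant = [s for s in wide.columns
                       if s not in ("normal_breast", "primary_tumor",
                                    "lymph_node")]
            shift = np.log(wide[distant].mean(axis=1) /
                           wide["primary_tumor"])
            effects.append(shift.mean())
        assert np.mean(effects) == pytest.approx(cfg.delta_met, rel=0.2)

    def test_null_channels_show_no_stage_trend(self):
        b = sc.generate_cohort(sc.CohortConfig(seed=6), geometry=False)
        agg, _ = cs.aggregate(ar.pool_bone_sites(b.attrs), b.dataset)
        res = cs.paired_tests(agg)
        null_mz = set(b.truth.channels.loc[
            b.truth.channels["role"].isin(["null_glycan", "unannotated"]),
            "mz"])
        null_res = res[res["channel"].isin(null_mz)]
        assert (null_res["p_adj"] < 0.05).mean() <= 0.05

    def test_bone_fucosylation_boost_expressed(self, planted_agg,
                                               planted_cohort):
        truth = planted_cohort.truth.channels
        bone_mz = truth.loc[truth["role"] == "bone_fuc", "mz"]
        sub = planted_agg[(planted_agg["category"] == "cancer")
                          & planted_agg["channel"].isin(bone_mz)]
        wide = sub.pivot_table(index="tma_id", columns="tissue_site",
                               values="mean_intensity")
        assert (wide["bone"] > wide["liver"]).mean() > 0.8

    def test_invalid_config_rejected_before_generation(self):
        with pytest.raises(ValueError):
            sc.CohortConfig(consistent_fraction=1.5)
        with pytest.raises(ValueError):
            sc.CohortConfig(sigma_pixel=-1)


@pytest.fixture(scope="module")
def channel_subset():
    b = sc.generate_cohort(small_cfg(), geometry=False)
    idx = np.arange(0, b.dataset.n_pixels, 997)[:6]
    return mp.MSIDataset(b.dataset.pixels.iloc[idx].reset_index(drop=True),
                         b.dataset.mz, b.dataset.intensities[idx])


class TestRawSpectra:
    def test_noiseless_single_channel_recovery_within_one_percent(self,
                                                                  channel_subset):
        raw_cfg = sc.RawSpectraConfig(noise_sd=0.0, baseline_amp=0.0)
        raw = sc.generate_raw_spectra(channel_subset, raw_cfg, seed=0)
        peaks = mp.PeakList(channel_subset.mz,
                            np.ones_like(channel_subset.mz))
        got = mp.extract_channels(raw, peaks, 0.25)
        rel = np.abs(got.intensities - channel_subset.intensities) \
            / channel_subset.intensities
        assert rel.max() < 0.01

    def test_deisotoping_leaves_one_peak_per_channel(self, channel_subset):
        raw = sc.generate_raw_spectra(channel_subset, seed=1)
        corrected = mp.baseline_correct_dataset(raw, 20)
        peaks = mp.pick_peaks(mp.mean_spectrum(corrected))
        d = np.abs(peaks.mz[:, None] - channel_subset.mz[None, :])
        hits = (d.min(axis=0) < 0.1).sum()
        assert hits == channel_subset.mz.size
        assert len(peaks) == channel_subset.mz.size  # no satellites survive

    def test_pure_noise_spectra_yield_no_peaks(self):
        pixels = pd.DataFrame({"tma_id": "T1", "x": np.arange(4), "y": 0})
        zero = mp.MSIDataset(pixels, np.array([1000.0, 1500.0]),
                             np.zeros((4, 2)))
        n_empty = 0
        for seed in range(10):
            raw = sc.generate_raw_spectra(zero, seed=seed)
            corrected = mp.baseline_correct_dataset(raw, 20)
            peaks = mp.pick_peaks(mp.mean_spectrum(corrected))
            n_empty += len(peaks) == 0
        assert n_empty >= 9  # no peaks at S/N 3 in >= 95% of seeds


class TestScoreRecovery:
    def fake_comparisons(self, truth, p_trend, p_null, direction=1):
        rows = []
        for _, ch in truth.channels.iterrows():
            p = p_trend if ch["role"] == "trend" else p_null
            rows.append({"site_a": "liver", "cat_a": "cancer",
                         "site_b": "primary_tumor", "cat_b": "cancer",
                         "channel": ch["mz"], "n_pairs": 17, "t": 5.0,
                         "df": 16, "p": p, "p_adj": p,
                         "direction": -direction})
        return pd.DataFrame(rows)

    def test_perfect_results_score_perfectly(self, planted_cohort):
        truth = planted_cohort.truth
        comp = self.fake_comparisons(truth, p_trend=0.001, p_null=0.9)
        rec = sc.score_recovery({"cohort_id": truth.cohort_id,
                                 "comparisons": comp}, truth)
        assert rec["sensitivity"] == 1.0 and rec["specificity"] == 1.0

    def test_shuffled_results_score_near_chance(self, planted_cohort):
        truth = planted_cohort.truth
        comp = self.fake_comparisons(truth, p_trend=0.001, p_null=0.9)
        rng = np.random.default_rng(0)
        comp["channel"] = rng.permutation(comp["channel"].to_numpy())
        rec = sc.score_recovery({"cohort_id": truth.cohort_id,
                                 "comparisons": comp}, truth)
        assert rec["sensitivity"] < 0.6

    def test_wrong_direction_not_counted_as_detection(self, planted_cohort):
        truth = planted_cohort.truth
        comp = self.fake_comparisons(truth, p_trend=0.001, p_null=0.9,
                                     direction=-1)
        rec = sc.score_recovery({"cohort_id": truth.cohort_id,
                                 "comparisons": comp}, truth)
        assert rec["sensitivity"] == 0.0

    def test_mismatched_cohort_ids_rejected(self, planted_cohort):
        with pytest.raises(ValueError):
            sc.score_recovery({"cohort_id": "other"}, planted_cohort.truth)

    def test_trend_confusion_matrix(self, planted_cohort):
        truth = planted_cohort.truth
        flags = dict(zip(truth.patients["tma_id"],
                         truth.patients["consistent"]))
        rec = sc.score_recovery({"cohort_id": truth.cohort_id,
                                 "trend_flags": flags}, truth)
        cm = rec["trend_confusion"]
        assert cm["fp"] == cm["fn"] == 0
        assert cm["tp"] + cm["tn"] == len(flags)


def test_truth_json_round_trip(tmp_path, tiny_cohort):
    path = tmp_path / "truth.json"
    tiny_cohort.truth.to_json(path)
    back = sc.SyntheticTruth.from_json(path)
    assert back.cohort_id == tiny_cohort.truth.cohort_id
    pd.testing.assert_frame_equal(
        back.patients, tiny_cohort.truth.patients, check_dtype=False)
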