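"""Synthetic single-patient TMA cohorts with known ground truth.

The generator emulates the statistical structure of a rapid-autopsy
N-glycan MSI cohort: 17 single-patient TMAs, each spanning normal
breast, primary tumor (PT), a sentinel lymph node and several distant
metastatic sites, with 4-5 circular 1.4 mm cores per tumor site on a
50 um pixel grid, each core subdivided into histology-category sectors.

Channel intensities follow a log-normal model with additive effects on
the log scale:

    log I = mu_c + b_p + f_cat * (traj(stage, c, p) + bone(site, c))
            + u_{p,site,cat,c} + v_{core,c} + e_i

where b_p is the per-patient baseline (interindividual variation),
traj the planted stage trajectory (high-mannose/trend channels rise
from normal through PT to distant metastases; the metastasis increment
is sign-flipped for the trend-inconsistent patient subset), bone() a
fucosylation boost restricted to skeletal sites, f_cat a histology
attenuation (cancer 1.0, cancer-mixed 0.8, cancer-associated stroma
0.5 — CAS resembling cancer — stroma/normal 0), u the TMA-level
(patient x site x category) heterogeneity that drives the paired-test
denominator, v a per-core effect, and e_i the pixel-level log noise.

Marker tables (e.g. an EpCAM-like IHC score) couple each patient's
met-minus-PT delta to the planted trend, with configurable coupling and
noise, so MSI-IHC concordance recovery can be scored against truth.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from glycotma import glycan_chem as gc
from glycotma.annotation_registry import AnnotationRegion, AffineTransform
from glycotma.msi_preprocess import (
    ISOTOPE_SPACING_DA,
    MSIDataset,
    Spectrum,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CohortConfig",
    "RawSpectraConfig",
    "SyntheticTruth",
    "CohortBundle",
    "default_channel_table",
    "generate_cohort",
    "generate_raw_spectra",
    "score_recovery",
    "write_cohort",
]

CATEGORY_ORDER = ("normal", "cancer", "cancer_mixed_cas",
                  "cancer_associated_stroma", "stroma", "necrosis")
CATEGORY_FACTOR = {"normal": 0.0, "cancer": 1.0, "cancer_mixed_cas": 0.8,
                   "cancer_associated_stroma": 0.5, "stroma": 0.0,
                   "necrosis": 0.2}
#: Angular sector fractions of a tumor core by histology category.
TUMOR_SECTORS = (("cancer", 0.45), ("cancer_mixed_cas", 0.35),
                 ("cancer_associated_stroma", 0.10), ("stroma", 0.05),
                 ("necrosis", 0.05))

BC_SUBTYPES = ("Lum", "Lum", "Lum/loss", "Lum/loss", "BLC", "BLC", "HER2+",
               "Lum", "Lum/loss", "BLC", "HER2+/loss", "Lum", "Lum/loss",
               "BLC", "Lum/loss", "Lum", "BLC")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generator settings (defaults emulate the study conditions).

    Sizes: 17 patients; sites normal breast, PT, lymph node plus distant
    metastases (two skeletal); 4-5 cores per tumor site (mean 4.5);
    1.4 mm cores on a 50 um grid (~600 pixels per core); 42 channels of
    which 10 carry the metastatic trend, 4 the bone fucosylation boost
    and 17 remain unannotated.

    Effects (log scale): delta_pt raises tumor over normal; delta_met is
    the distant-metastasis increment over PT (default 0.25 = 0.5 x the
    pixel-level log SD); delta_bone the skeletal fucosylation boost.
    sigma_patient/sigma_tma/sigma_core/sigma_pixel are the nested log-SDs.
    effect_scale multiplies all planted effects (0 gives a null cohort).
    """

    n_patients: int = 17
    distant_sites: tuple[str, ...] = ("bone", "rib", "lung", "liver",
                                      "diaphragm", "adrenal")
    bone_like_sites: tuple[str, ...] = ("bone", "rib")
    cores_per_tumor_site: tuple[int, int] = (4, 5)
    cores_normal_breast: int = 4
    core_diameter_um: float = 1400.0
    pixel_pitch_um: float = 50.0
    n_channels: int = 42
    n_trend_channels: int = 10
    n_bone_channels: int = 4
    n_unannotated_channels: int = 17
    delta_pt: float = 0.3
    delta_met: float = 0.25
    delta_bone: float = 0.4
    sigma_patient: float = 0.6
    sigma_tma: float = 0.15
    sigma_core: float = 0.10
    sigma_pixel: float = 0.5
    consistent_fraction: float = 12 / 17
    effect_scale: float = 1.0
    ihc_couplings: tuple[tuple[str, float, float], ...] = (
        ("EpCAM_IHC", 1.0, 0.08),   # (marker, coupling, noise SD)
        ("cMYC_FISH", 0.0, 0.30),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_channels <= 0:
            raise ValueError("counts must be positive")
        if min(self.sigma_patient, self.sigma_tma, self.sigma_core,
               self.sigma_pixel) < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0 <= self.consistent_fraction <= 1:
            raise ValueError("consistent_fraction must lie in [0, 1]")
        used = (self.n_trend_channels + self.n_bone_channels
                + self.n_unannotated_channels)
        if used > self.n_channels:
            raise ValueError("channel role counts exceed n_channels")

    @property
    def sites(self) -> tuple[str, ...]:
        return ("normal_breast", "primary_tumor", "lymph_node",
                *self.distant_sites)

    def stage_of(self, site: str) -> int:
        """0 normal, 1 PT, 2 lymph node, 3 distant metastasis."""
        base = {"normal_breast": 0, "primary_tumor": 1, "lymph_node": 2}
        return base.get(site, 3)


# --- channel roster ----------------------------------------------------------

_TREND_NAMED = ["Hex5HexNAc2", "Hex6HexNAc2", "Hex7HexNAc2", "Hex8HexNAc2",
                "Hex9HexNAc2", "Hex10HexNAc2", "Hex11HexNAc2", "Hex12HexNAc2",
                "Hex5HexNAc4", "Hex6HexNAc5"]
_BONE_NAMED = ["Hex3dHex1HexNAc4", "Hex4dHex1HexNAc4", "Hex5dHex1HexNAc4",
               "Hex6dHex1HexNAc5"]
_MIN_CHANNEL_SPACING_DA = 4.0  # keeps isotope envelopes of neighbours apart


def default_channel_table(cfg: CohortConfig | None = None) -> pd.DataFrame:
    """The cohort's channel roster: mz, composition, role, glycan_class.

    Roles: 'trend' (metastatic-path increase; high-mannose series plus
    two complex glycans), 'bone_fuc' (fucosylated, boosted in skeletal
    sites), 'null_glycan' (assigned but flat), 'unannotated' (m/z with no
    composition match, carried through statistics unannotated).
    """
    cfg = cfg or CohortConfig()
    match_cfg = gc.MatchConfig()
    rows: list[dict] = []

    def add(comp_str: str, role: str) -> None:
        comp = gc.parse_composition(comp_str)
        rows.append({"mz": gc.sodiated_mz(comp), "composition": comp_str,
                     "role": role,
                     "glycan_class": gc.classify(comp).value})

    for name in _TREND_NAMED[: cfg.n_trend_channels]:
        add(name, "trend")
    for name in _BONE_NAMED[: cfg.n_bone_channels]:
        add(name, "bone_fuc")

    def spaced(mz: float) -> bool:
        return all(abs(mz - r["mz"]) >= _MIN_CHANNEL_SPACING_DA for r in rows)

    n_null = (cfg.n_channels - cfg.n_trend_channels - cfg.n_bone_channels
              - cfg.n_unannotated_channels)
    used = {r["composition"] for r in rows}
    for comp in gc.enumerate_compositions(match_cfg):
        if n_null <= 0:
            break
        s = gc.format_composition(comp)
        mz = gc.sodiated_mz(comp)
        if s in used or not spaced(mz):
            continue
        rows.append({"mz": mz, "composition": s, "role": "null_glycan",
                     "glycan_class": gc.classify(comp).value})
        used.add(s)
        n_null -= 1

    theo = np.array(sorted(gc.sodiated_mz(c)
                           for c in gc.enumerate_compositions(match_cfg)))
    n_un = cfg.n_unannotated_channels
    for mz in np.arange(705.0, match_cfg.mz_max - 5.0, 1.37):
        if n_un <= 0:
            break
        j = int(np.searchsorted(theo, mz))
        near = min(
            abs(theo[k] - mz) for k in (j - 1, j) if 0 <= k < theo.size
        )
        if near > match_cfg.tolerance_da + 0.15 and spaced(mz):
            rows.append({"mz": float(mz), "composition": "",
                         "role": "unannotated", "glycan_class": ""})
            n_un -= 1

    tab = pd.DataFrame(rows).sort_values("mz").reset_index(drop=True)
    if len(tab) != cfg.n_channels:
        raise ValueError("could not assemble the requested channel roster")
    return tab


# --- truth -------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside every generated cohort."""

    cohort_id: str
    channels: pd.DataFrame       # mz, composition, role, mu, delta_pt/met/bone
    patients: pd.DataFrame       # tma_id, bc_subtype, baseline, consistent
    couplings: dict              # marker -> {coupling, noise_sd, channels}
    config: dict

    def to_json(self, path) -> None:
        doc = {
            "cohort_id": self.cohort_id,
            "channels": self.channels.to_dict(orient="list"),
            "patients": self.patients.to_dict(orient="list"),
            "couplings": self.couplings,
            "config": self.config,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            cohort_id=doc["cohort_id"],
            channels=pd.DataFrame(doc["channels"]),
            patients=pd.DataFrame(doc["patients"]),
            couplings=doc["couplings"],
            config=doc["config"],
        )


@dataclass
class CohortBundle:
    """Everything a downstream run needs, plus the generating truth."""

    dataset: MSIDataset          # channel-mode intensities, all patients
    attrs: pd.DataFrame          # ground-truth pixel attribute table
    annotations: list[AnnotationRegion]
    fiducials: pd.DataFrame
    markers: pd.DataFrame
    truth: SyntheticTruth
    transform: AffineTransform


# --- generation --------------------------------------------------------------

def _core_layout(cfg: CohortConfig, rng: np.random.Generator):
    """Place cores on a per-TMA grid and enumerate their pixels and sectors.

    Pixel membership is arithmetic (distance to the core center at most
    0.997 x radius, so every generated pixel is strictly inside the
    64-gon polygon approximation of the core), and category sectors are
    angular wedges with a fixed offset so pixel centers never sit on a
    sector ray in practice.
    """
    r_px = cfg.core_diameter_um / 2 / cfg.pixel_pitch_um
    r_sel = 0.997 * r_px
    core_grid_pitch = int(math.ceil(2 * r_px)) + 4
    angle_offset = 0.1379
    sector_edges = np.cumsum([0.0] + [f for _, f in TUMOR_SECTORS]) * 2 * np.pi
    sector_cats = np.array([c for c, _ in TUMOR_SECTORS], dtype=object)

    # pixel template shared by every core (centers are half-integers
    # relative to the integer core center)
    half = core_grid_pitch / 2
    span = np.arange(core_grid_pitch)
    txs, tys = np.meshgrid(span, span)
    pcx = txs + 0.5 - half
    pcy = tys + 0.5 - half
    inside = np.hypot(pcx, pcy) <= r_sel
    t_x, t_y = txs[inside], tys[inside]
    ang = (np.arctan2(pcy[inside], pcx[inside]) - angle_offset) % (2 * np.pi)
    t_sec = np.clip(np.searchsorted(sector_edges, ang, side="right") - 1,
                    0, len(TUMOR_SECTORS) - 1)
    n_t = t_x.size

    parts = []
    n_cores_total = 0
    for p in range(cfg.n_patients):
        tma = f"TMA{p + 1:02d}"
        core_slot = 0
        for s, site in enumerate(cfg.sites):
            if site == "normal_breast":
                n_cores = cfg.cores_normal_breast
            else:
                lo, hi = cfg.cores_per_tumor_site
                n_cores = int(rng.integers(lo, hi + 1))
            for k in range(n_cores):
                col, row = core_slot % 10, core_slot // 10
                cx = col * core_grid_pitch + half
                cy = row * core_grid_pitch + half
                core_slot += 1
                gid = n_cores_total
                n_cores_total += 1

                if site == "normal_breast":
                    cats = np.full(n_t, "normal", dtype=object)
                    sec = np.zeros(n_t, dtype=int)
                    rids = np.full(n_t, f"{tma}_{site}_c{k}_normal",
                                   dtype=object)
                else:
                    sec = t_sec
                    cats = sector_cats[t_sec]
                    lut = np.array([f"{tma}_{site}_c{k}_{c}"
                                    for c in sector_cats], dtype=object)
                    rids = lut[t_sec]
                parts.append(pd.DataFrame({
                    "tma_id": tma, "p_idx": p,
                    "x": t_x + col * core_grid_pitch,
                    "y": t_y + row * core_grid_pitch,
                    "tissue_site": site, "s_idx": s,
                    "category": cats, "core_id": gid, "region_id": rids,
                    "core_cx": cx, "core_cy": cy, "sector": sec,
                }))
    pix = pd.concat(parts, ignore_index=True)
    return pix, n_cores_total, r_px, angle_offset


def _core_polygons(pix: pd.DataFrame, cfg: CohortConfig, r_px: float,
                   angle_offset: float) -> list[AnnotationRegion]:
    """Build annotation polygons (in slide um) matching the pixel layout."""
    pitch = cfg.pixel_pitch_um
    regions: dict[str, AnnotationRegion] = {}
    sector_edges = np.cumsum([0.0] + [f for _, f in TUMOR_SECTORS]) * 2 * np.pi
    cores = pix.drop_duplicates("region_id")
    for _, row in cores.iterrows():
        center = Point(row.core_cx * pitch, row.core_cy * pitch)
        circle = center.buffer(r_px * pitch, quad_segs=16)
        if row.tissue_site == "normal_breast":
            poly = circle
        else:
            i = int(row.sector)
            a0 = sector_edges[i] + angle_offset
            a1 = sector_edges[i + 1] + angle_offset
            arc = np.linspace(a0, a1, 24)
            wedge = Polygon(
                [(center.x, center.y)]
                + [(center.x + 2.5 * r_px * pitch * np.cos(a),
                    center.y + 2.5 * r_px * pitch * np.sin(a)) for a in arc]
            )
            poly = circle.intersection(wedge)
        regions[row.region_id] = AnnotationRegion(
            region_id=row.region_id,
            tissue_site=row.tissue_site,
            category=row.category,
            polygon=poly,
            tma_id=row.tma_id,
        )
    return list(regions.values())


def generate_cohort(cfg: CohortConfig | None = None,
                    geometry: bool = True) -> CohortBundle:
    """Generate a full synthetic cohort (deterministic for a given config).

    geometry=False skips polygon construction (the pixel layout and the
    ground-truth attribute table are unchanged), useful for statistical
    simulation loops that do not exercise the coregistration stage.
    """
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    chan = default_channel_table(cfg)
    n_ch = len(chan)
    roles = chan["role"].to_numpy()
    mz = chan["mz"].to_numpy()

    # per-channel base log abundance, spread over ~an order of magnitude
    mu = np.linspace(np.log(0.5), np.log(2.0), n_ch)

    scale = cfg.effect_scale
    d_pt = np.where(roles == "trend", scale * cfg.delta_pt, 0.0)
    d_met = np.where(roles == "trend", scale * cfg.delta_met, 0.0)
    d_bone = np.where(roles == "bone_fuc", scale * cfg.delta_bone, 0.0)

    # --- patient-level draws (order fixed for determinism) ---
    baselines = rng.normal(0.0, cfg.sigma_patient, cfg.n_patients)
    n_consistent = int(round(cfg.consistent_fraction * cfg.n_patients))
    consistent = np.zeros(cfg.n_patients, dtype=bool)
    consistent[rng.permutation(cfg.n_patients)[:n_consistent]] = True
    sign = np.where(consistent, 1.0, -1.0)

    pix, n_cores, r_px, angle_offset = _core_layout(cfg, rng)

    sites = cfg.sites
    stages = np.array([cfg.stage_of(s) for s in sites])
    bone_like = np.array([s in cfg.bone_like_sites for s in sites])
    catfac = np.array([CATEGORY_FACTOR[c] for c in CATEGORY_ORDER])

    # effect cube E[p, s, cat, c]
    u = rng.normal(0.0, cfg.sigma_tma,
                   (cfg.n_patients, len(sites), len(CATEGORY_ORDER), n_ch))
    traj = np.zeros((cfg.n_patients, len(sites), n_ch))
    for s in range(len(sites)):
        st = stages[s]
        if st >= 1:
            traj[:, s, :] += d_pt[None, :]
        if st == 3:
            traj[:, s, :] += sign[:, None] * d_met[None, :]
        if bone_like[s]:
            traj[:, s, :] += d_bone[None, :]
    E = (baselines[:, None, None, None]
         + catfac[None, None, :, None] * traj[:, :, None, :]
         + u)

    v = rng.normal(0.0, cfg.sigma_core, (n_cores, n_ch))

    # --- markers ---
    marker_rows = []
    couplings = {}
    coupled_channels = chan.loc[chan["role"] == "trend", "mz"].tolist()
    for marker, coupling, noise_sd in cfg.ihc_couplings:
        pt_vals = rng.normal(2.0, 0.3, cfg.n_patients)
        eps = rng.normal(0.0, noise_sd, cfg.n_patients)
        met_vals = pt_vals + coupling * sign * scale * cfg.delta_met + eps
        for p in range(cfg.n_patients):
            marker_rows.append({"patient_id": f"TMA{p + 1:02d}",
                                "marker": marker,
                                "pt_value": pt_vals[p],
                                "met_value": met_vals[p]})
        couplings[marker] = {"coupling": coupling, "noise_sd": noise_sd,
                             "channels": coupled_channels if coupling else []}
    markers = pd.DataFrame(marker_rows)

    # --- pixel intensities ---
    cat_idx = pd.Categorical(pix["category"],
                             categories=CATEGORY_ORDER).codes
    log_int = (mu[None, :]
               + E[pix["p_idx"].to_numpy(), pix["s_idx"].to_numpy(), cat_idx]
               + v[pix["core_id"].to_numpy()]
               + rng.normal(0.0, cfg.sigma_pixel, (len(pix), n_ch)))
    intensities = np.exp(log_int)

    subtypes = [BC_SUBTYPES[p % len(BC_SUBTYPES)] for p in range(cfg.n_patients)]
    pixels = pix[["tma_id", "x", "y"]].copy()
    pixels["bc_subtype"] = [subtypes[p] for p in pix["p_idx"]]
    dataset = MSIDataset(pixels.reset_index(drop=True), mz, intensities,
                         cfg.pixel_pitch_um)

    attrs = pix[["tma_id", "x", "y", "tissue_site", "category",
                 "region_id"]].copy().reset_index(drop=True)
    attrs["bc_subtype"] = pixels["bc_subtype"].to_numpy()

    annotations = (_core_polygons(pix, cfg, r_px, angle_offset)
                   if geometry else [])

    # slide um -> grid: pure scaling by the pixel pitch
    transform = AffineTransform(1 / cfg.pixel_pitch_um, 0.0, 0.0,
                                1 / cfg.pixel_pitch_um, 0.0, 0.0)
    span = (pix[["x", "y"]].to_numpy().max() + 10) * cfg.pixel_pitch_um
    fid_slide = np.array([[0, 0], [span, 0], [0, span], [span, span]], float)
    fid_grid = transform.apply(fid_slide)
    fiducials = pd.DataFrame(
        np.column_stack([fid_slide, fid_grid]),
        columns=["slide_x_um", "slide_y_um", "grid_x", "grid_y"])

    truth_channels = chan.copy()
    truth_channels["mu"] = mu
    truth_channels["delta_pt"] = d_pt
    truth_channels["delta_met"] = d_met
    truth_channels["delta_bone"] = d_bone
    truth_patients = pd.DataFrame({
        "tma_id": [f"TMA{p + 1:02d}" for p in range(cfg.n_patients)],
        "bc_subtype": subtypes,
        "baseline": baselines,
        "consistent": consistent,
    })
    truth = SyntheticTruth(
        cohort_id=f"synthetic-seed{cfg.seed}-p{cfg.n_patients}",
        channels=truth_channels,
        patients=truth_patients,
        couplings=couplings,
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(cfg).items()},
    )
    return CohortBundle(dataset, attrs, annotations, fiducials, markers,
                        truth, transform)


# --- raw profile spectra -----------------------------------------------------

@dataclass(frozen=True)
class RawSpectraConfig:
    """Continuous-spectrum synthesis settings.

    Each channel contributes a Gaussian peak at its m/z (scaled so the
    summed bin intensities equal the channel intensity) plus isotope
    satellites at +k*1.00335 Da with geometrically decreasing areas, on
    top of a smooth exponentially decaying baseline and additive noise.
    """

    mz_min: float = 700.0
    mz_max: float = 3000.0
    mz_step: float = 0.02
    fwhm_da: float = 0.2
    n_isotopes: int = 3
    isotope_decay: float = 0.5
    baseline_amp: float = 0.05
    baseline_scale_da: float = 800.0
    noise_sd: float = 0.005

    @property
    def sigma_da(self) -> float:
        return self.fwhm_da / (2 * math.sqrt(2 * math.log(2)))


def generate_raw_spectra(
    dataset: MSIDataset,
    raw_cfg: RawSpectraConfig | None = None,
    seed: int = 0,
) -> MSIDataset:
    """Render a channel-mode dataset into per-pixel profile spectra."""
    raw_cfg = raw_cfg or RawSpectraConfig()
    rng = np.random.default_rng(seed)
    axis = np.arange(raw_cfg.mz_min, raw_cfg.mz_max, raw_cfg.mz_step)
    cents = dataset.mz
    if np.any(np.diff(np.sort(cents)) < 2 * raw_cfg.fwhm_da):
        logger.warning("generate_raw_spectra: channels closer than 2x FWHM "
                       "will overlap")
    sigma = raw_cfg.sigma_da
    norm = raw_cfg.mz_step / (sigma * math.sqrt(2 * math.pi))

    # sparse per-channel peak templates on the shared axis
    templates = []
    for c in cents:
        cols, vals = [], []
        for k in range(0, raw_cfg.n_isotopes + 1):
            mz0 = c + k * ISOTOPE_SPACING_DA
            lo = np.searchsorted(axis, mz0 - 5 * sigma)
            hi = np.searchsorted(axis, mz0 + 5 * sigma)
            if lo >= hi:
                continue
            g = norm * (raw_cfg.isotope_decay ** k) * np.exp(
                -0.5 * ((axis[lo:hi] - mz0) / sigma) ** 2)
            cols.append(np.arange(lo, hi))
            vals.append(g)
        templates.append((np.concatenate(cols) if cols else np.array([], int),
                          np.concatenate(vals) if vals else np.array([])))

    baseline = raw_cfg.baseline_amp * np.exp(
        -(axis - raw_cfg.mz_min) / raw_cfg.baseline_scale_da)
    out = np.empty((dataset.n_pixels, axis.size))
    for i in range(dataset.n_pixels):
        spec = baseline.copy()
        for j, (cols, vals) in enumerate(templates):
            if cols.size:
                spec[cols] += dataset.intensities[i, j] * vals
        if raw_cfg.noise_sd > 0:
            spec += rng.normal(0.0, raw_cfg.noise_sd, axis.size)
        out[i] = np.maximum(spec, 0.0)
    return MSIDataset(dataset.pixels.copy(), axis, out, dataset.pixel_pitch_um)


# --- recovery scoring --------------------------------------------------------

def score_recovery(
    results: dict,
    truth: SyntheticTruth,
    alpha: float = 0.05,
) -> dict:
    """Score pipeline outputs against the generating truth.

    results is a dict with any of:
      'cohort_id'     (required) the id of the cohort the results came from
      'comparisons'   paired-test table (from cohort_stats.paired_tests)
      'trend_flags'   per-patient consistency flags (tma_id -> bool)
      'concordance'   concordance table (from ihc_concordance)

    Detection of a planted trend channel = a significant (adjusted
    p < alpha), correctly directed result in at least one distant-site
    cancer vs primary-tumor cancer contrast.
    """
    if results.get("cohort_id") != truth.cohort_id:
        raise ValueError("results and truth come from different cohorts")
    report: dict = {"cohort_id": truth.cohort_id}
    trend_mz = set(truth.channels.loc[truth.channels["role"] == "trend",
                                      "mz"])
    null_mz = set(truth.channels.loc[
        truth.channels["role"].isin(["null_glycan", "unannotated"]), "mz"])
    distant = {s for s in truth.config["distant_sites"]}
    distant = (distant - {"rib", "spine", "vertebra"}) | (
        {"bone"} if distant & {"bone", "rib", "spine", "vertebra"} else set())

    comp = results.get("comparisons")
    if comp is not None and len(comp):
        mask_ab = (comp["site_a"].isin(distant) & (comp["cat_a"] == "cancer")
                   & (comp["site_b"] == "primary_tumor")
                   & (comp["cat_b"] == "cancer"))
        mask_ba = ((comp["site_a"] == "primary_tumor")
                   & (comp["cat_a"] == "cancer")
                   & comp["site_b"].isin(distant) & (comp["cat_b"] == "cancer"))
        sub = comp[mask_ab | mask_ba].copy()
        # orient so direction +1 means metastasis above PT
        sub["met_dir"] = np.where(mask_ba[mask_ab | mask_ba],
                                  sub["direction"], -sub["direction"])
        sig_up = sub[(sub["p_adj"] < alpha) & (sub["met_dir"] > 0)]
        sig_any = sub[sub["p_adj"] < alpha]
        detected = set(sig_up["channel"])
        flagged = set(sig_any["channel"])
        tp = len(trend_mz & detected)
        report["sensitivity"] = tp / len(trend_mz) if trend_mz else float("nan")
        report["specificity"] = (
            1 - len(null_mz & flagged) / len(null_mz) if null_mz
            else float("nan"))
        report["direction_accuracy"] = (
            len(trend_mz & detected) / max(len(trend_mz & flagged), 1))
        report["n_significant"] = int((comp["p_adj"] < alpha).sum())
        report["fraction_significant"] = float(
            (comp["p_adj"] < alpha).mean())

    flags = results.get("trend_flags")
    if flags is not None:
        truth_flags = dict(zip(truth.patients["tma_id"],
                               truth.patients["consistent"]))
        common = [t for t in flags if t in truth_flags]
        tp = sum(bool(flags[t]) and truth_flags[t] for t in common)
        tn = sum(not flags[t] and not truth_flags[t] for t in common)
        fp = sum(bool(flags[t]) and not truth_flags[t] for t in common)
        fn = sum(not flags[t] and truth_flags[t] for t in common)
        report["trend_confusion"] = {"tp": tp, "tn": tn, "fp": fp, "fn": fn}
        report["trend_fraction_recovered"] = (
            (tp + fp) / len(common) if common else float("nan"))
        report["trend_fraction_true"] = (
            sum(truth_flags.values()) / len(truth_flags))

    conc = results.get("concordance")
    if conc is not None and len(conc):
        ranks = {}
        for marker, block in conc.groupby("marker"):
            coupled = set(truth.couplings.get(marker, {}).get("channels", []))
            if not coupled:
                continue
            block = block.set_index("channel")
            cp = block.loc[block.index.isin(coupled), "p_adj"]
            np_ = block.loc[~block.index.isin(coupled), "p_adj"]
            ranks[marker] = bool(len(cp) and len(np_)
                                 and cp.max() <= np_.min())
        report["coupled_channels_rank_lowest"] = ranks
    return report


# --- serialization -----------------------------------------------------------

def write_cohort(bundle: CohortBundle, outdir) -> dict[str, Path]:
    """Write every downstream input format plus truth under outdir."""
    from glycotma.annotation_registry import write_annotations

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    wide = bundle.dataset.pixels.copy()
    for j, mz in enumerate(bundle.dataset.mz):
        wide[f"mz_{mz:.4f}"] = bundle.dataset.intensities[:, j]
    paths["channels"] = outdir / "channels.tsv"
    wide.to_csv(paths["channels"], sep="\t", index=False)

    paths["attrs"] = outdir / "attrs_truth.tsv"
    bundle.attrs.to_csv(paths["attrs"], sep="\t", index=False)

    paths["annotations"] = outdir / "regions.geojson"
    write_annotations(bundle.annotations, paths["annotations"])

    paths["fiducials"] = outdir / "fiducials.tsv"
    bundle.fiducials.to_csv(paths["fiducials"], sep="\t", index=False)

    paths["markers"] = outdir / "markers.tsv"
    bundle.markers.to_csv(paths["markers"], sep="\t", index=False)

    paths["truth"] = outdir / "truth.json"
    bundle.truth.to_json(paths["truth"])
    return paths


def read_cohort_channels(path, pixel_pitch_um: float = 50.0) -> MSIDataset:
    """Read the wide channels.tsv written by write_cohort."""
    df = pd.read_csv(path, sep="\t")
    mz_cols = [c for c in df.columns if c.startswith("mz_")]
    mz = np.array([float(c[3:]) for c in mz_cols])
    pixels = df.drop(columns=mz_cols)
    return MSIDataset(pixels, mz, df[mz_cols].to_numpy(float), pixel_pitch_um)
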