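# Default pipeline configuration for `glycotma run --config configs/default.yaml`.
# Every value below is also the library default; edit a copy rather than
# relying on overrides at the command line for reproducible runs.

outdir: glycotma_run
seed: 1
stages: [simulate, label, stats, concordance, report]
trend_channel: Hex6HexNAc2      # high-mannose glycan profiled along the path

cohort:
  n_patients: 17                # single-patient TMAs
  distant_sites: [bone, rib, lung, liver, diaphragm, adrenal]
  bone_like_sites: [bone, rib]  # receive the fucosylation boost; pooled later
  cores_per_tumor_site: [4, 5]  # uniform 4-5 cores, mean 4.5
  cores_normal_breast: 4
  core_diameter_um: 1400.0      # 1.4 mm cylindrical cores
  pixel_pitch_um: 50.0          # 50 um MSI raster
  n_channels: 42                # picked m/z channels
  n_trend_channels: 10          # rise from PT to distant metastases
  n_bone_channels: 4            # fucosylated, boosted in skeletal sites
  n_unannotated_channels: 17    # m/z with no composition assignment
  delta_pt: 0.3                 # log-scale tumor-over-normal effect
  delta_met: 0.25               # log-scale distant-met-over-PT effect
                                # (= 0.5 x sigma_pixel)
  delta_bone: 0.4               # log-scale skeletal fucosylation boost
  sigma_patient: 0.6            # per-patient baseline log-SD
  sigma_tma: 0.15               # patient x site x category log-SD
  sigma_core: 0.10              # per-core log-SD
  sigma_pixel: 0.5              # pixel-level log-SD (intratumor heterogeneity)
  consistent_fraction: 0.70588  # 12/17 patients carry the upward trend
  effect_scale: 1.0             # 0 gives a null cohort
  ihc_couplings:                # [marker, coupling, noise SD]
    - [EpCAM_IHC, 1.0, 0.08]
    - [cMYC_FISH, 0.0, 0.30]

stats:
  min_pixels: 150               # minimum spectra per annotation region
  min_tmas: 5                   # minimum TMAs per (site, category) combo
  alpha: 0.05                   # significance on BH-adjusted p
  bh_family: per_pair           # adjust across channels within a combo pair

match:
  tolerance_da: 0.3             # composition matching tolerance
  mz_min: 700.0                 # acquisition window
  mz_max: 3000.0
  hex_bounds: [3, 12]           # enumeration bounds per residue
  hexnac_bounds: [2, 8]
  dhex_bounds: [0, 4]
  neuac_bounds: [0, 4]
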