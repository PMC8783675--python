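# glycotma

Spatial N-glycomics of metastatic breast cancer tissue microarrays:
a tested pipeline from MALDI mass spectrometry imaging (MSI) pixels and
pathology annotations to glycan-annotated m/z channels, paired cohort
statistics along the metastatic path, and MSI–IHC concordance.

## The problem

In stage IV breast cancer, single-patient tissue microarrays (TMAs)
assembled from rapid autopsies place normal breast, primary tumor (PT),
lymph node, and many distant metastasis cores from one patient on one
block. MALDI-MSI of PNGaseF-released N-glycans records a mass spectrum
at every 50 μm pixel; a pathologist annotates the co-registered H&E
image with tissue site and histology category (normal, stroma,
cancer-associated stroma, cancer mixed with CAS, cancer, necrosis).
The scientific questions are spatial and paired within patients: do
specific N-glycan classes — high-mannose (Hex≥5HexNAc2), fucosylated
(dHex≥1), sialylated (NeuAc≥1), tri-/tetra-antennary branched
(HexNAc≥5) — rise from normal breast → PT → distant metastases, is bone
metastasis distinguished by core-fucosylation, and do per-patient glycan
shifts track IHC markers such as EpCAM?

The package is aimed at imaging mass-spectrometrists and computational
pathologists who need this analysis reproducible end to end. Because
clinical raw MSI data of this kind are rarely shareable, a synthetic
cohort generator with known ground truth is a first-class component:
every stage is tested against truth, and the statistical operating
characteristics (false discovery rate, power, trend recovery) are
measured rather than assumed.

## What it computes

* **Glycan mass annotation.** Candidate compositions
  Hex_h dHex_f HexNAc_n NeuAc_s (h∈[3,12], n∈[2,8], f,s∈[0,4], with the
  trimannosyl-chitobiose core n≥2, h≥3) are enumerated and matched to
  observed channels as sodiated adducts,
  m/z([M+Na]⁺) = Σ cᵢ·mᵢ + m(H₂O) + m(Na⁺), within ±0.3 Da.
  E.g. Hex5HexNAc2 → 1257.42, Hex6HexNAc2 → 1419.5,
  Hex5dHex1HexNAc4 → 1809.64.
* **Preprocessing.** Per-pixel convolution baseline correction (width-20
  minimum filter + moving average), TIC normalization, mean spectrum,
  Gaussian smoothing, S/N ≥ 3 peak picking against a peak-to-peak style
  noise band, deisotoping (+k·1.00335 Da satellites), and ±0.25 Da
  channel integration.
* **Coregistration.** Least-squares affine transform from fiducial
  pairs; point-in-polygon labeling of pixel centers, smallest-area
  polygon wins on overlap; skeletal sites (bone, rib, spine, vertebra)
  pooled into "bone".
* **Cohort statistics.** Mean intensity per (patient, site, category,
  channel) with the ≥150-pixel annotation filter and ≥5-TMA combination
  filter; two-tailed paired t tests for every channel and every pair of
  retained combinations, paired within patients; Benjamini–Hochberg
  adjustment per combination pair; unit-variance PCA of pixel spectra
  with 95% confidence ellipses; per-patient metastatic-path trend
  profiles with a strict distant-mets > PT consistency rule.
* **MSI–IHC concordance.** Per-patient (pooled metastases − PT) deltas
  over cancer-bearing annotations, dichotomized at zero; disagreements
  with a marker's binary profile tested by the exact two-sided binomial
  test against Binomial(n, ½), BH-adjusted across channels.

## Worked example

Run the numbered analysis scripts in order (about a minute each; large
intermediates go to `scratch/`, summary tables to `results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_raw_spectra.py
python analysis/03_label_pixels.py
python analysis/04_cohort_statistics.py
python analysis/05_ihc_concordance.py
python analysis/06_operating_characteristics.py
```

The default 17-patient cohort (seed 1) prints:

```
cohort synthetic-seed1-p17:
  17 patients, 9 tissue sites each
  688 cores, 3168 annotation regions
  423808 pixels x 42 m/z channels (50 um pitch)
  trend-consistent patients (truth): 12/17
```

Preprocessing the rendered raw spectra recovers every planted channel
(`picked 42 peaks at S/N 3 after deisotoping; recall 1.000`, noiseless
channel integration within 0.34%), and polygon labeling reproduces the
generator's ground-truth pixel labels exactly
(`agreement with generator truth: 1.0000`). The statistics stage then
reports:

```
aggregated to 10710 (patient, site, category, channel) means; 1860 regions below 150 pixels removed, 1308 kept
15 of 15 (site, category) combinations present in >= 5 TMAs
4410 paired tests; 288 significant at adjusted p < 0.05 covering 22 of 42 channels
Hex6HexNAc2 (m/z 1419.5) metastatic-path trend: 12/17 patients consistent (71%)
```

i.e. the per-patient trend rule recovers exactly the 12-of-17 (71%)
consistent fraction the generator planted. The concordance stage ranks
the EpCAM-coupled channels first (`best channels ['1257.4', '1419.5',
'1663.6']` with 0 disagreements in 17 patients) while the uncoupled
FISH marker yields nothing, and the operating-characteristics sweep
measures a null significant fraction of 0.0007 (nominal 0.05) and
sensitivity 0.94 for planted 0.5-SD effects.

The same pipeline is scriptable as a single seeded run:

```bash
glycotma run --config configs/default.yaml --seed 1 --out glycotma_run
```

which writes the result tables plus a `manifest.json` with per-stage
filter counts and output checksums (two runs with the same config are
checksum-identical). Individual stages are exposed as
`glycotma simulate|preprocess|label|stats|concordance|report|score`.

## Layout

```
src/glycotma/          library: glycan_chem, msi_preprocess,
                       annotation_registry, cohort_stats,
                       ihc_concordance, synthetic_cohort, pipeline, cli
analysis/              numbered narrative drivers over the library
tests/                 pytest suite incl. acceptance criteria
configs/default.yaml   the shipped default run configuration
docs/methods.md        model, parameters, numerical choices, limitations
```
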