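# Methods

## Glycan composition arithmetic

A released N-glycan is represented by its monosaccharide composition
(n_Hex, n_HexNAc, n_dHex, n_NeuAc). Residue masses are derived from
atomic monoisotopic masses (Hex C6H10O5 = 162.05282 Da, HexNAc C8H13NO5
= 203.07937 Da, dHex C6H10O4 = 146.05791 Da, NeuAc C11H17NO8 =
291.09542 Da); the neutral molecule adds one water (18.01056 Da) and the
detected species is the sodiated cation [M+Na]⁺ (+22.98922 Da, sodium
minus one electron). Observed channels are matched against all
enumerated valid compositions (chitobiose core: HexNAc ≥ 2, Hex ≥ 3;
bounds Hex ≤ 12, HexNAc ≤ 8, dHex ≤ 4, NeuAc ≤ 4, within m/z 700–3000)
at a ±0.3 Da tolerance. The tolerance absorbs the systematic offset
between TOF-calibrated observed values and theoretical masses (e.g. the
1257.56 channel vs the theoretical 1257.42 for Hex5HexNAc2); no mass
recalibration is attempted. Structural classes are assigned with the
fixed precedence high-mannose (HexNAc = 2, Hex ≥ 5, no dHex/NeuAc) >
fucosylated (dHex ≥ 1) > sialylated (NeuAc ≥ 1) > branched (HexNAc ≥ 5)
> other complex/hybrid, which makes the partition deterministic; the
non-exclusive feature flags are exposed separately. Channels with no
match within tolerance are carried through all statistics unannotated.

## Spectral preprocessing

Processing order: per-pixel baseline correction → per-pixel TIC
normalization → overall mean spectrum → Gaussian smoothing → peak
picking with deisotoping → per-pixel channel extraction around the
picked centroids.

*Baseline.* "Convolution" baseline correction is implemented as a
width-20-point minimum filter followed by a width-20-point moving
average of that lower envelope, subtracted and floored at zero. Whether
such a filter should operate on index width or m/z width is a genuinely
open choice; data points are used here.

*Noise and the S/N threshold.* The signal-to-noise threshold (default
3) is applied against a peak-to-peak style noise level, as in classic
MALDI peak-picking software: σ is estimated robustly by a sliding
501-point median/MAD (×1.4826), then scaled by √(2 ln w) ≈ 3.5, the
expected half peak-to-peak excursion of Gaussian noise over a w-point
window. A threshold of 3 × σ alone is not usable on a 10⁵-bin axis: the
expected number of chance local maxima above 3σ is in the dozens, so a
pure-noise spectrum would always yield "peaks". Peak height is measured
above the sliding median (which tracks residual baseline offsets) and
the same bound is required of the peak prominence, which suppresses
noise-split twin maxima on the flanks of wide peaks. Centroids are
intensity-weighted over ±2 smoothing sigmas.

*Deisotoping.* For singly charged sodiated glycans below m/z 3000 the
monoisotopic peak is the lowest-m/z member of its envelope. A retained
peak within ±0.1 Da of (monoisotopic + k·1.00335 Da), k ∈ {1,2,3}, of a
more intense lower-m/z peak is removed, walking up the envelope while
intensities decrease.

*Channel extraction.* Channel intensity is the summed intensity within
±0.25 Da of the centroid — below the 0.3 Da identification tolerance and
wide enough to cover > 99.5% of a FWHM 0.2 Da peak. Every m/z bin is
assigned to its nearest centroid only, so the per-pixel channel sums
can never exceed the pixel TIC even when windows overlap.

## Coregistration and labeling

The H&E-to-MSI map is a least-squares affine transform fitted from ≥ 3
non-collinear fiducial pairs (slide μm → grid units). The MSI grid is
0-based, x = column, y = row, pixel centers at (x+0.5, y+0.5) grid
units; imzML coordinates (1-based) are shifted on read. Labeling is
point-in-polygon on the pixel center with closed boundaries — at 50 μm
pixels against 1.4 mm cores, area-overlap weighting would change almost
nothing. Overlapping annotations are resolved in favour of the
smallest-area polygon (pathologists refine sub-regions inside coarse
ones); equal-area ties fall back to the lexicographically smallest
region id with a warning. Annotations carrying a TMA id label only that
TMA's pixels, since every TMA is its own slide. Landmark/affine
registration is fixed here; intensity-based registration is out of
scope.

## Cohort statistics

Pixels are averaged to one value per (patient/TMA, tissue site,
histology category, channel). Two coverage filters precede testing:
annotation regions with fewer than 150 pixels are dropped, and
(site, category) combinations present in fewer than 5 TMAs are
discarded (both thresholds inclusive at the boundary). Regions
surviving the filter are pooled pixel-weighted within a combination.

For every unordered pair of retained combinations and every channel, a
two-tailed paired t test is computed over the TMAs containing both
members (pairs with fewer than 5 common TMAs are skipped); pairing
within patients cancels the large interindividual baselines. If the
paired differences are identically zero the test is reported as t = 0,
p = 1 rather than 0/0. BH adjustment is applied across the channels of
one combination pair (the loop-over-channels family); a global family
across all pairs is available as an option since the choice of family
is not uniquely dictated. The full matrix of pairs is reported, which is
a superset of the featured contrasts (normal breast vs PT; PT vs bone,
lung, liver; bone vs liver).

PCA of individual pixel spectra is computed after centering and
unit-variance scaling (i.e. on the correlation structure);
zero-variance channels are dropped with a warning. Group ellipses are
95% confidence regions from the 2-df chi-square quantile applied to the
per-group score covariance in the PC1/PC2 plane.

*Trend profiles.* For a named channel, per-patient stage means are
computed over cancer-bearing annotations (cancer, cancer mixed with
CAS) along normal breast → PT → lymph node → distant metastases, with
all sites beyond the lymph node pooled pixel-weighted. The sentinel
lymph node is excluded from the distant pool because it behaves like an
intermediate stage with PT-like levels. A patient is trend-consistent
when the pooled distant-metastasis mean strictly exceeds the PT mean;
ties count as inconsistent. This is a deliberately crisp formalization
used for synthetic recovery, not a claim about how a pathologist would
call a trend by eye.

## MSI–IHC concordance

Per patient, the channel mean over all pooled metastases (every
non-PT, non-normal site, the lymph node included) minus the PT mean is
computed over cancer-bearing annotations, then dichotomized at zero
with exact zeros mapped to 0 (the boundary assignment is configurable
but fixed by default). The number of positions where the glycan and
marker binary profiles disagree is tested against Binomial(n, ½) with
an exact two-sided test that doubles the smaller tail (capped at 1);
for the symmetric null this equals summing both tails. Small
disagreement counts indicate concordance. BH correction runs across
channels within each marker. Sidedness is configurable since only the
test family is fixed by convention.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not the biophysics of a TOF instrument. Channel intensity for pixel i
in region r of patient p is log-normal with additive log-scale effects:

    log I = μ_c + b_p + f_cat(r) · [traj(stage(r), c, p) + bone(site(r), c)]
            + u_{p,site,cat,c} + v_{core,c} + e_i

| parameter | default | meaning |
|---|---|---|
| μ_c | log 0.5 … log 2 | per-channel base abundance (spread ~1 decade) |
| b_p | SD 0.6 | per-patient (per-TMA) baseline |
| δ_pt | 0.3 | tumor-over-normal effect, PT and lymph node stages |
| δ_met | 0.25 | distant-metastasis increment over PT (0.5 × σ_pixel) |
| δ_bone | 0.4 | fucosylation boost in skeletal sites |
| σ_tma | 0.15 | patient × site × category heterogeneity |
| σ_core | 0.10 | per-core effect |
| σ_pixel | 0.5 | pixel-level intratumor heterogeneity |

Ten of 42 channels (a high-mannose series plus two complex glycans)
carry the stage trajectory; four fucosylated channels carry the bone
boost; the rest — including 17 channels placed at m/z values that match
no composition — are null. Category factors attenuate effects (cancer
1.0, cancer mixed with CAS 0.8, CAS 0.5 — CAS resembling cancer —
necrosis 0.2, stroma and normal 0). A configured fraction of patients
(default 12/17) is trend-consistent; the rest have the δ_met increment
sign-flipped, which makes the per-patient consistency call a crisp
ground truth (zeroing instead of flipping would leave the call at coin-
toss mercy of σ_tma). Geometry: 1.4 mm circular cores on a 50 μm grid
(~615 pixels per core), 4–5 cores per tumor site (mean 4.5), tumor
cores split into angular category sectors (cancer 45%, cancer+CAS 35%,
CAS 10%, stroma 5%, necrosis 5%); the small sectors deliberately fall
under the 150-pixel filter, mirroring how sparse stromal annotations
drop out of real cohorts. Pixel membership is computed arithmetically
at 0.997 × radius so every generated pixel lies strictly inside the
64-gon polygon written to GeoJSON — polygon labeling therefore
reproduces the generating truth exactly, which is asserted end to end.

IHC-style markers couple the per-patient met−PT delta to the planted
trend: marker delta = coupling × (±δ_met) + Normal(0, σ_IHC). The
default EpCAM-like marker uses coupling 1.0 with σ_IHC = 0.08 (sign
agreement ≈ 0.97 per patient); the FISH-like marker is uncoupled. With
17 patients, a strict "all coupled channels rank above all null
channels" property is binomially fragile when many channels are
coupled: the maximum of k disagreement counts at agreement 0.9 collides
with the minimum of 32 null counts at Binomial(17, ½) far too often (a
direct tail computation gives ~0.79 success at k = 10). The ranking
recovery property is therefore exercised with k = 3 coupled channels at
the default coupling strength, where the same computation puts success
above 0.95; the power and FDR properties use the full k = 10
configuration.

Raw-spectrum rendering places a Gaussian peak (FWHM 0.2 Da, scaled so
the summed bin intensities equal the channel value) at each channel's
sodiated m/z on a 0.02 Da grid over m/z 700–3000, plus isotope
satellites at +k·1.00335 Da with geometrically halving areas, an
exponentially decaying baseline, and additive Gaussian noise. Channel
centroids in the default roster are kept ≥ 4 Da apart so neighbouring
isotope envelopes cannot interact with deisotoping.

What the generator does **not** emulate: TOF peak-shape asymmetry and
resolution drift, detector saturation, matrix clusters, mass-calibration
drift across TMAs, morphologically realistic histology, spatial
autocorrelation of intensities within a region (pixels are exchangeable
given their region), and non-sodium adducts. Passing tests therefore
demonstrate that the statistical machinery is correct and well
calibrated under the assumed data model — not that the model captures
every pathology of real acquisitions.

## Statistical operating characteristics

Because the pipeline aggregates ~600-pixel regions before testing,
pixel noise is negligible at the TMA level and the paired-test
denominator is dominated by σ_tma. The experiments are run at the full
default scale (17 patients, 9 sites, ~424k pixels, 42 channels;
about 2–3 s per cohort):

* *False discovery:* on null cohorts (all effects zeroed; 50 seeds) the
  mean fraction of BH-significant comparisons is ~0.001, far below the
  0.05 bound — under a global null BH controls the family-wise rate, so
  the per-comparison rate is necessarily small.
* *Power:* planted δ_met = 0.25 (0.5 × σ_pixel) in 10/42 channels with
  every patient consistent (the clean planted-effect condition; the
  12/17 mixture is a different, deliberately harder ground truth used
  for trend recovery) gives sensitivity ≳ 0.9 with correct direction,
  where detection means a BH-significant, correctly signed result in at
  least one distant-site-vs-PT cancer contrast.
* *Trend recovery:* cohorts generated at 12/17 consistency are
  recovered by the strict trend rule within ±2 patients across seeds.

## Known limitations

Composition matching cannot resolve isomers (Hex5HexNAc2 vs any other
arrangement of the same residues) and considers only [M+Na]⁺; the
affine registration assumes rigid slide-to-grid geometry; the paired t
test treats per-TMA means as exchangeable across patients despite
log-normal marginals (acceptable at n = 17 by symmetry of the paired
differences, and verified empirically by the null calibration); and the
BH family convention changes which marginal results cross 0.05 — both
families are computed, only the per-pair default is asserted.
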