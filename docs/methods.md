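# Methods

This note documents the models implemented in `lbmct`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical conventions. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Volumes and geometry

Volumes are 3D arrays in `(slice, row, column)` order with per-axis
spacing in mm (`ImageVolume`). NIfTI-1 is the native format; the round
trip write→read is lossless for voxel values, shape and spacing (spacing
to float32 precision, the NIfTI header's own limit). DICOM series are
read-only: slices are ordered by the projection of ImagePositionPatient
onto the slice normal (never by filename), inter-slice gaps must agree
within 1%, and RescaleSlope/Intercept are applied at read time so all
downstream code sees Hounsfield units. The axial crop used to form the
limited-coverage (LC) region is a half-open, 0-based slice interval
`[lo, hi)`; half-open intervals compose exactly and make empty ranges
detectable. Voxel volume is the product of the spacings divided by 1000
(mm³ → mL).

## Fat volumetry

Adipose tissue is segmented by the standard CT adipose window
**−190 ≤ HU ≤ −30, both bounds inclusive**. The mask is binary:
partial-volume voxels count whole, so measured volume carries an O(h)
surface discretization error that vanishes with voxel size h (verified on
the phantom, below). Fat volume is voxel count × voxel volume; fat mass
uses the average adipose density **0.923 kg/L**.

An optional body mask (largest 26-connected component above −500 HU,
morphologically closed and hole-filled) excludes detached fat-density
objects such as the scanner couch. It is **off by default**: the base
method is defined without one, and the mask policy is recorded in the
CLI report so provenance is explicit. The LC boundaries (top of thorax,
distal ischium) are supplied as slice indices by the user; no automatic
landmark detection is attempted.

## LBM models

* **James equation** (`lbm_james`): male 1.10·W − 120·(W/H)²; female
  1.07·W − 148·(W/H)²; W in kg, H in cm. For fixed H the male curve peaks
  at W* = 1.10·H²/240 and decreases beyond it; in extreme body habitus
  the result can be non-positive. Implausible values (≤0 or >W) are
  returned **flagged, never clamped** — clamping would hide exactly the
  pathology that motivates the image-derived alternative.
* **Limited-coverage model** (`lbm_lc`): LBM = W − (α + β·FV_LC) with
  defaults α = 2.892 kg, β = 1.3337 kg/L. **FV_LC is in litres**: the
  coefficients are only dimensionally consistent with litres (the
  predicted fat mass at the development-cohort mean FV_LC of 11.084 L is
  17.67 kg, matching that cohort's mean fat mass of 17.71 kg to 0.2%,
  whereas cm³ would give tonnes). `FatVolumetryResult.fat_volume_l`
  performs the mL→L conversion.
* **Whole-body reference** (`lbm_wholebody_reference`): W − FM_WB, the
  reference standard when whole-body CT is available.
* **Refitting** (`fit_fat_model`): ordinary least squares of FM_WB on
  FV_LC (scipy.stats.linregress), returning α, β, Pearson r and n. Sexes
  are pooled by default; fit subsets for per-sex models. Identities
  guaranteed to numerical precision: the fitted line passes through the
  sample means, and lbm_lc + predicted fat mass = W exactly.

## PERCIST machinery

* **SUL conversion**: SUL = SUV×LBM/W; switching LBM algorithm is the
  pure ratio SUL_b = SUL_a × LBM_b/LBM_a (weight cancels).
* **Lesion segmentation**: iterative adaptive thresholding with
  T_{k+1} = w·max + (1−w)·mean over the current mask (default w = 0.5),
  new mask = voxels ≥ T_{k+1} 26-connected to the seed maximum; stops
  when |ΔT| < tol (default 1e-4) or at max_iter (default 100, then a
  warning with the last mask). The threshold sequence is recorded; the
  converged threshold satisfies the fixpoint equation to tol.
* **SUL_peak**: maximum over sphere centers inside the lesion mask of the
  mean SUL in a 12-mm-diameter (≈1 cm³) voxelized sphere; membership is
  center-in-sphere; the sphere may extend past the lesion (PERCIST
  convention) but not past the image (geometry error). Implemented as a
  correlation with the normalized sphere kernel.
* **Background**: spherical liver ROI (default 30 mm diameter), sample
  SD (ddof = 1, matching clinical software; ddof = 0 available).
  Measurability: SUL_peak ≥ 1.5·liver_mean + 2·SD (the standard PERCIST
  parse; the alternate 1.5·(mean + 2·SD) is behind `strict_parse`), or
  SUL_peak > 2.0×blood-pool mean when the liver is abnormal.
* **Classification**: PMR iff change ≤ −30% and |Δ| ≥ 0.8 SUL; PMD iff
  change ≥ +30% and |Δ| ≥ 0.8; else SMD; thresholds inclusive. The 0.8
  minimal-absolute-change gate is the PERCIST 1.0 default and is
  configurable. CMR is not emitted: the package targets cohorts with
  residual avid disease at follow-up, where the three-class scheme is the
  native output. Target lesion = hottest lesion per scan, ties broken by
  lesion_id so selection is deterministic; the follow-up target may be a
  different lesion than baseline's.

## Agreement statistics

Cohen's κ is unweighted by default (linear/quadratic weights behind a
flag); κ = (Po−Pe)/(1−Pe) and returns NaN with a warning when Pe = 1.
The Wilcoxon signed-rank test runs on ordinal codes PMD=1 < SMD=2 < PMR=3
with a **policy-tagged** zero handling: discard (default) or Pratt, and
either a tie-corrected normal approximation without continuity correction
or an exact sign-flip enumeration (dynamic programming over doubled
midranks, n ≤ 25). The policy is always part of the result object because
different software conventions give visibly different p-values on heavily
tied ordinal data. Bland–Altman uses sample SD and bias ± 1.96·SD limits.
The threshold-band analysis classifies a patient as "in band w" iff
||pct| − 30| ≤ w (inclusive), reporting cumulative bands and the shells
between consecutive half-widths with discordant fractions to 1 d.p.

## Synthetic data

* **CT phantom**: nested ellipsoids (fat shell over lean core, in air),
  voxel membership center-in-shape, so the voxel-count ground truth is
  exact and the analytic truth is 4/3·π·(abc_outer − abc_inner). Tissue
  HU noise is truncated per tissue (fat to [−190, −30]) so intensity
  noise can never change window membership — geometry error and
  intensity error stay separable. A perfectly centred ellipsoid on an
  even-spacing grid enjoys lucky error cancellations, so convergence
  measurements average |relative error| over a few sub-voxel placements
  (`center_offset_mm`); with that, the mean error decreases monotonically
  over 4→2→1 mm and is far below 2% at 1 mm (recomputed by the
  acceptance script). An optional detached fat-density slab emulates the
  couch for body-mask tests.
* **PET phantom**: uniform background, spherical lesion, designated
  liver sphere with configurable mean/SD.
* **Regression cohort** (`make_cohort`): n = 199 by default with a
  93/199 female fraction; sex-specific weight/height normals
  (men 63.5±15.1 kg, 166.6±6.7 cm; women 56.2±9.2 kg, 156.3±5.9 cm);
  FV_LC lognormal with mean 11.084 L and σ_log = 0.55 (spanning roughly
  3–30 L, matching the reported cohort range); FM_WB = α + β·FV_LC +
  N(0, 1.9 kg), which yields a sample Pearson r near 0.977. Rows with
  FM outside (0, W) are resampled (bounded); the active constraint
  slightly shifts the FV mean, which the tests account for.
* **Paired-timepoint PERCIST cohort** (`make_percist_cohort`): baseline
  SUL_peak lognormal (median 6, σ_log 0.35) floored at 4.0 g/mL — the
  measurability criterion already implies ≈3.6 for a typical 2.0±0.3
  liver, and the floor additionally guarantees the 0.8 gate never masks
  a ≥30% change, so simulated discordance is purely threshold-driven.
  True percent change mixes a response arm (−39.78±18.52%) and a
  progression arm (+34.03±19.18%) with p(decrease) = 0.6. LBM changes
  between timepoints follow a categorical mixture of the three observed
  mechanisms — LBM loss (PE −7.2±2.2% vs LC −2.8±1.8%), LBM gain
  (+5.7±1.5 vs +1.8±1.7), and divergent weight-gain/fat-loss
  (+1.8±1.0 vs −4.8±1.9) — with weights 16:5:6 and draws truncated at
  ±3 SD; `lbm_change_scale=0` freezes LBM. Truncation makes the set of
  reachable LBM-ratio factors bounded, so the band of |percent change|
  where discordance is algebraically possible is computable
  (`reachable_discordance_band`) and tested.

What the generators do **not** emulate: scanner physics and
reconstruction, anatomical realism (organs, arms, contrast phases),
lesion heterogeneity and partial-volume blur, correlated weight/LBM
trajectories (the joint distribution of weight change and LBM change is
exposed as spec parameters, not asserted). Passing tests therefore
validate the arithmetic, segmentation logic and statistics — not
performance on real scans.

## Numerical conventions and degenerate inputs

Inclusive bounds everywhere a threshold is named (HU window, ±30%,
minimal absolute change, band edges). Empty masks, zero-variance
regressors, zero-variance paired differences, all-zero Wilcoxon
differences, and spheres that do not fit the volume each raise a typed
error (or return p = 1 with a note, for the Wilcoxon case). All
generators are bit-reproducible for a fixed seed and spec.

## Known limitations

No resampling or registration; no automatic anatomical landmarking of
the LC range; no visceral/subcutaneous compartmentalization; no CMR
class; no κ confidence intervals; the manual "adjust the tumour surface"
step of clinical workstations has no algorithmic description and is out
of the automated path. The default fat-model coefficients come from a
single-scanner, single-ethnicity development cohort with few obese
subjects; refit `fit_fat_model` for other populations.
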