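# Methods

## Signal model and leakage correction

The DSC signal of a voxel is modelled as
`S(t) = S0 · exp(−TE · ΔR2*(t))`; inverting gives
`ΔR2*(t) = −ln(S(t)/S0)/TE` with `S0` the mean over the pre-bolus
baseline frames. Voxels whose baseline mean or any sample is non-positive
cannot be log-converted; they are excluded from the brain mask and all
downstream maps are zero there.

Contrast extravasation in blood-brain-barrier-disrupted tissue adds a T1
shortening term that drives late-bolus ΔR2\* below zero. The correction
regresses each voxel curve on two regressors built from the reference
curve `R(t)` (the frame-wise mean ΔR2\* over non-enhancing brain):

    ΔR2*_vox(t) ≈ k1·R(t) − k2·∫₀ᵗ R(τ)dτ

by ordinary least squares over the post-onset window (first frame where
`R` exceeds 10% of its peak, through the last frame). `k1` is the
dimensionless perfusion scale; `k2` (1/s per unit integrated reference)
absorbs leakage. The corrected curve adds the fitted `k2` term back and
CBV is its trapezoidal time integral. On noiseless data this fit is
exact: the synthetic generator constructs voxel curves from the same
two-regressor structure, so recovery to numerical precision is the
designed round-trip, and the tests verify it against a per-voxel
normal-equations solve.

Reference region: the whole-brain mask minus the enhancing VOI, not a
literal contralateral hemisphere — hemisphere labelling is undefined for
phantoms and the mean over non-enhancing brain is the convention the
two-parameter model assumes. It is configurable (any mask, e.g.
normal-appearing white matter, can be passed).

Negative corrected CBV values are retained until classification (they
become negative ratios and land in FTB_low); clipping earlier would bias
the reference mean.

## Scaling

Ratio scaling divides CBV by the mean over the same non-enhancing
reference mask, making reference tissue exactly 1.0; the FTB thresholds
1.0 and 1.6 are defined on this scale. Ratio scaling is idempotent and
invariant to any global positive rescaling of CBV — the conservation
property the tests assert.

Histogram-landmark standardisation (piecewise-linear mapping through
matched decile landmarks, strictly monotone, end-slope extrapolation
beyond the outer landmarks) is provided for cross-scanner harmonisation.
The published landmark sets for commercial implementations are not
public, so the default model is the identity and the thresholds are
applied to plain reference-normalised ratios; both paths are exposed.

## Segmentation and QC

ΔT1 = gain-aligned post-contrast minus pre-contrast T1, where the gain is
the ratio of within-brain median intensities (robust to the small
enhancing lesion, invariant to global receiver gain). The VOI is the
union of 26-connected supra-threshold components (Otsu threshold within
the brain by default; a fixed threshold can be forced) of at least
`min_component_vox` voxels (default 10), closed with a 1-voxel ball.
Three advisory QC flags automate reader rejection rules: signal-invalid
voxels inside the VOI; overlap of the VOI with supplied non-pathological
structure masks above 2% of the VOI; more than 5% of supra-threshold ΔT1
voxels left outside the VOI. The 2% and 5% tolerances are this package's
choices for an automated desk-scale check, configurable at call time.
Rigid registration is deliberately thin (integer-translation SSD search):
phantoms are generated co-registered and identity alignment is the tested
path.

## FTB classification

FTB_low: rCBV ≤ 1.0; FTB_mid: 1.0 < rCBV < 1.6; FTB_high: rCBV ≥ 1.6.
Boundary values belong to the outer classes by definition — a
measure-zero distinction in theory but a real one for discretised data,
so it is fixed as stated. Negative ratios go to FTB_low. Summaries carry
exact integer voxel counts; percentages always sum to 100 by
construction. Rendering follows the red/yellow/blue convention
(high/mid/low) in an RGB overlay volume plus a per-class histogram table.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes,
with known truth at every level:

* **Acquisition**: TR 1.35 s, TE 43 ms, 75 frames, 1.8×1.8×5.0 mm voxels,
  8 baseline frames. The default grid is 32×32×15 voxels — a desk-scale
  matrix chosen so a 59-patient cohort generates and processes in
  seconds; the processing itself is resolution-agnostic.
* **Bolus**: a peak-normalised gamma-variate (shape 3, scale 4 s, peak
  ΔR2\* 6 /s → a ~23% first-pass signal drop in reference tissue at TE
  43 ms) with onset two frames after the baseline window. The clinical
  dual-bolus injection is simulated as a single first pass; preload
  effects are folded into the leakage coefficient, which is a free
  parameter (`k2_range`, default 0–0.05).
* **Lesion**: an ellipsoid inside an ellipsoidal brain; its voxels are
  partitioned into the three classes by largest-remainder rounding of the
  planted fractions, each voxel's true rCBV drawn uniformly from its
  class interval. Default intervals (0.30–0.95, 1.05–1.55, 1.65–2.80)
  keep a small guard band around the thresholds, reflecting that the
  literature-chosen thresholds sit between perfusion regimes rather than
  in the middle of a tissue class. Background brain is reference tissue
  (ratio 1, no leakage); outside the brain is zero-signal air.
* **Cohort**: 35 TP and 24 TRA patients by default, per-patient class
  fractions Dirichlet-distributed about group means 44/19/37% (TP) and
  60/19/21% (TRA). The concentration (default 3.0) was calibrated by
  Monte Carlo so the planted FTB_high AUROC at these group sizes is
  centred near the clinically reported 0.70 and falls inside the reported
  95% CI band (0.56–0.84) in about 95% of seeded cohorts — the group
  means pin the location, the dispersion is otherwise free.
* **Noise**: additive Gaussian on the signal, default 2% of baseline
  (SNR 50). Real DSC noise is Rician and spatially correlated; at this
  SNR the Gaussian approximation is adequate, but passing tests say
  nothing about low-SNR or motion/susceptibility-artefact regimes. Other
  unmodelled features: arterial input function variation, multi-echo
  readout, partial-volume mixing at lesion borders, registration error
  between sequences (volumes are generated co-registered).

Every draw flows from one seeded `numpy` generator; a cohort is a pure
function of its specification.

## Statistics

* Mann-Whitney U uses midranks; p-values by full enumeration of group
  assignments for combined n ≤ 12 (valid under ties), otherwise the
  tie-corrected, continuity-corrected normal approximation.
* AUC is computed by the rank/U identity (equal to the trapezoidal area
  under the empirical ROC; ties count one half); tests cross-check
  against scikit-learn and a brute-force pair count.
* Bootstrap CIs are stratified (resampling within each outcome class)
  percentile intervals — the text-faithful choice; DeLong-type intervals
  are deliberately not claimed.
* The Youden scan evaluates all midpoints between adjacent distinct
  scores plus the extremes; positivity is strict inequality
  ("more than 24%" / "more than 59%" as the fixed clinical rules state).
  Ties on J break toward higher specificity, then the lower cutoff.
* The AUROC comparison resamples patients (paired by default, since both
  burden fractions are measured on the same lesions; an unpaired option
  exists), computes the AUC difference per resample, and refers
  D = (observed difference)/(bootstrap SD) to the standard normal,
  two-sided — the pROC-style bootstrap test. The report states the
  subtraction convention explicitly rather than relying on the sign.
* No multiplicity adjustment is applied; the report says so.

## Problem sizes and determinism

Default analyses use the 32×32×15 grid, 59-patient cohorts, 2,000
bootstrap resamples for CIs and 10,000 for the AUROC comparison. The test
suite's Monte-Carlo studies use 500 replicates (1,000 and 500 resamples
respectively), chosen as the package's own trade-off between statistical
resolution and a fast default test run. All bootstrap and generator seeds
are explicit arguments; reports are byte-identical across reruns at a
fixed seed.

## Known limitations

* The simulator plants the same two-regressor structure the correction
  fits, so leakage-recovery tests validate the numerics, not the
  adequacy of the Boxerman model for real tissue curves.
* Landmark standardisation defaults to identity; absolute agreement with
  any specific commercial standardisation pipeline is not claimed.
* Segmentation replaces a semi-automatic human-corrected workflow with
  Otsu + component filtering; it is exercised only on phantom-like
  contrast distributions.
* The clinical performance figures (AUROC ≈ 0.7, cutoffs 24%/59%) derive
  from a 59-patient study whose data are not public; the synthetic cohort
  reproduces their statistical structure, not the patients.
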