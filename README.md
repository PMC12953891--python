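# ftburden

Fractional tumor burden (FTB) quantification from dynamic susceptibility
contrast (DSC) perfusion MRI, for the post-treatment surveillance of
glioblastoma: distinguishing true tumor progression (TP) from
treatment-related abnormalities (TRA) such as pseudoprogression and
radionecrosis, which look alike on conventional contrast-enhanced imaging.

The package is aimed at imaging scientists who want a transparent, fully
seeded reimplementation of the FTB post-processing chain — including a
synthetic phantom cohort generator with voxel-level ground truth, so every
stage can be validated without patient data.

## Method

1. **ΔR2\* conversion** — each voxel's DSC signal `S(t)` becomes a
   relaxation-rate change `ΔR2*(t) = −ln(S(t)/S0)/TE`, with `S0` the
   pre-bolus baseline mean.
2. **Leakage correction** — blood-brain-barrier disruption lets contrast
   extravasate, contaminating ΔR2\* with a T1 term. Each voxel curve is
   regressed on the non-enhancing whole-brain reference curve and its
   running integral,

   `ΔR2*_vox(t) ≈ k1 · ΔR2*_ref(t) − k2 · ∫₀ᵗ ΔR2*_ref(τ) dτ`,

   the two-parameter linear model of Boxerman-type correction; `k1` scales
   perfusion, `k2` captures leakage.
3. **rCBV** — cerebral blood volume is the time integral of the corrected
   curve, divided by the mean over non-enhancing brain so reference tissue
   is 1.0 (optional histogram-landmark standardisation is available).
4. **Lesion VOI** — the enhancing lesion is segmented on the ΔT1 map
   (gain-aligned post- minus pre-contrast T1) with Otsu thresholding,
   26-connected component filtering and morphological closing; automated
   QC flags mirror a reader's rejection rules.
5. **FTB classes** — VOI voxels are classified by rCBV ratio:
   FTB_low ≤ 1.0 < FTB_mid < 1.6 ≤ FTB_high; the percent of VOI voxels
   per class is the per-patient burden profile.
6. **Diagnostics** — Mann-Whitney U per class, ROC/AUROC with stratified
   bootstrap percentile CIs, Youden-index cutoffs, fixed clinical rules
   (FTB_high > 24% ⇒ TP; FTB_low > 59% ⇒ TRA) and a bootstrap D-test
   comparing the two correlated AUROCs.

Voxelwise steps are exposed as scikit-learn style estimators
(`DeltaR2Star`, `LeakageCorrector`, `RatioNormalizer`,
`LandmarkStandardizer`, `FtbVoxelClassifier`, `YoudenThresholdClassifier`)
so they compose with sklearn pipelines; module-level functions wrap them
for whole NIfTI volumes.

## Worked example

```python
import numpy as np
import ftburden as fb

acq = fb.AcquisitionParams()          # TR 1.35 s, TE 43 ms, 75 frames
lesion = fb.LesionSpec(
    center_vox=(15.5, 15.5, 7.0), radius_vox=(6, 6, 3),
    frac_low=0.44, frac_mid=0.19, frac_high=0.37,
)
patient = fb.build_patient(lesion, "TP", acq, noise_sd=0.02,
                           rng=np.random.default_rng(0))
result = fb.quantify_patient(patient.dsc, patient.t1_pre, patient.t1_post, acq)
s = result.summary
print(f"planted fractions : {100 * patient.truth.fracs_true}")
print(f"measured percent  : low={s.pct_low:.1f} mid={s.pct_mid:.1f} high={s.pct_high:.1f}")
print(f"VOI volume        : {s.voi_volume_ml:.1f} mL  QC flags: {result.qc_flags or 'none'}")
```

```
planted fractions : [44.10377358 18.86792453 37.02830189]
measured percent  : low=44.0 mid=19.4 high=36.5
VOI volume        : 6.9 mL  QC flags: none
```

The phantom planted 44.1/18.9/37.0% of lesion voxels in the three classes;
at baseline SNR 50 the full pipeline (leakage fit, segmentation,
thresholding) recovers 44.0/19.4/36.5% — within half a percentage point
per class. A TP lesion like this one would be called progression by the
fixed rule because more than 24% of its voxels are FTB_high.

The same chain is available from the shell:

```bash
ftburden simulate --out cohort/            # 59 seeded NIfTI phantoms
ftburden quantify cohort/tp_000            # one patient → maps + summary
ftburden run-all --out cohort/             # simulate + quantify + evaluate
```

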