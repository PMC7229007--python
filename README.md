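# pctpoly

Pseudo-CT synthesis from dual-contrast MRI by per-region polynomial
regression on binned joint intensities.

Given co-registered volume triplets per patient — two MRI volumes acquired
with different sequences (MR1, MR2) and a CT volume on the same voxel grid —
plus region labels (bony / soft / mixed, with an optional excluded overlay),
the package:

1. **normalizes** MR intensities across the cohort with per-patient
   multiplicative correction factors;
2. **bins** each region's voxels on an Nbin × Nbin grid over joint
   (MR1, MR2) intensity space and computes per-bin mean CT numbers,
   imputing empty bins from the nearest filled bin (ties averaged, imputed
   regression weight 10% of the donor's);
3. **fits** one total-degree-≤ n bivariate polynomial per region by
   count-weighted least squares over bin centers (inputs rescaled to [0, 1],
   SVD solve with relative cutoff 1e−10), or alternatively a bilinear
   lookup over the bin-center lattice;
4. **synthesizes** a pseudo-CT volume (predictions clamped to
   [−1000, 2000] HU, air set to −1000 HU exactly);
5. **evaluates** it: overall and per-region MAE / RMS error, a weighted-MAE
   region accounting, an error-budget decomposition into fit error and
   within-bin CT spread (which add exactly in quadrature under per-bin
   prediction), and a point-to-point dose passing rate within a percent
   tolerance;
6. **cross-validates** with a leave-one-out driver reporting per-cycle and
   mean ± sd summaries.

A synthetic phantom module generates deterministic multi-patient cohorts
(nested-ellipsoid geometry, smooth random dual-channel intensity fields,
known noisy intensity→HU ground truth, per-patient scanner gains, excluded
region corruption), so the whole pipeline is testable end-to-end without
patient data.

## CLI

All volumes are NIfTI; labels are integer-coded NIfTI
(0=outside, 1=bony, 2=soft, 3=mixed) with the excluded overlay as a
separate binary volume.

```sh
# generate a 6-patient phantom cohort (also writes cohort.yaml)
pctpoly simulate --out data/ --patients 6 --seed 17

# train per-region models (config lists patients and parameters)
pctpoly train --config data/cohort.yaml --out models.json

# synthesize a pseudo-CT for a target patient
pctpoly predict --model models.json --mr1 mr1.nii --mr2 mr2.nii \
    --labels labels.nii --out pct.nii

# HU error report, and point-to-point dose comparison
pctpoly evaluate --pct pct.nii --rct ct.nii --labels labels.nii --report report.csv
pctpoly compare-dose --dose-pct dp.nii --dose-rct dr.nii --labels labels.nii \
    --reference-gy 56

# leave-one-out cross-validation over the cohort
pctpoly loocv --config data/cohort.yaml --out runs/loocv
```

Config keys mirror the flags: `nbin` (default 200), `degree` (default 30),
`model_type` (`polynomial` | `interpolation`), `sequences`
(`both` | `MR1` | `MR2`), `segmentation` on/off, `use_excluded` on/off,
`axis_max` override, `empty_weight_fraction`, dose tolerance/reference.

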