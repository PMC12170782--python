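# gbmphen

Multiparametric MRI quantification and diffusion-phenotype cohort
analysis for post-chemoradiation, IDH-wildtype glioblastoma.

Post-chemoradiation glioblastomas split into two biologically distinct
groups by their diffusion MRI phenotype.  The ADC histogram inside the
contrast-enhancing (CE) tumor is modelled as a two-Gaussian mixture

    f(x) = w_lo·N(x; µ_lo, σ_lo²) + w_hi·N(x; µ_hi, σ_hi²),

and **ADC_L = µ_lo**, the mean of the lower (cellular) mode, classifies
each lesion as *high-ADC_L* (ADC_L ≥ 1240 µm²/s, the phenotype
associated with favorable anti-VEGF response) or *low-ADC_L*.  The
package quantifies, on one common grid per lesion:

- **ADC** (µm²/s) from a b = 0 / b = 1000 s/mm² DWI pair;
- **rCBV** from DSC perfusion with bidirectional leakage correction
  (ΔR2*_meas = k1·x̄ − k2·∫x̄·e^(−kep·Δt), grid search over kep, linear
  least squares in (k1, k2)), normalized to the whole-brain median;
- **MTR_asym @ 3 ppm** (%) from amine CEST z-spectra, with B0
  correction via z-spectrum k-means clustering + Lorentzian fitting of
  the water dip, band integration over 3.0 ± 0.2 ppm, and a
  ΔB0 > 0.3 ppm quality gate;
- **qT2 / qT2*** (ms) from 4-echo spin-and-gradient-echo (SAGE) EPI by
  the closed-form piecewise gradient/spin-echo solution;
- **deltaT1**, the normalized post- minus pre-contrast T1w subtraction;

then assembles one profile row per lesion (ROI medians, CE volume,
RANO measurability, covariates) and runs the cohort battery:
Mann-Whitney group tests with Benjamini-Hochberg correction, Fisher's
exact tests for locations and covariates, a qT2-adjusted regression of
MTR_asym, Pearson correlations, and k = 2 k-means on (ADC_L, rCBV,
MTR_asym) with concordance against the 1240 µm²/s threshold.

A signal-level **synthetic cohort generator** (87 lesions, 37 high /
50 low, with group-dependent ROI medians, volumes and location counts)
provides ground truth for every stage, so the whole pipeline is
verifiable without patient data.  It is first-class, tested code — see
`docs/methods.md` for what it does and does not emulate.

## Worked example

`examples/` holds one narrative script per capability.  For instance,
B0-corrected amine CEST (`examples/03_cest_mtrasym.py`):

```text
target MTR_asym       : 2.36 %
estimated ΔB0         : +0.100 ppm (true +0.100)
uncorrected median    : 2.83 %
corrected median      : 2.35 %
flagged voxels (>0.3) : 0
```

A 0.1 ppm field offset shifts the water dip and biases the ±3 ppm band
average by ~0.5 percentage points; clustering the z-spectra, fitting
the centroid water dip and resampling the spectra restores the true
2.36% amine asymmetry.  Cohort-level statistics
(`examples/05_cohort_statistics.py`) on a generated 87-lesion table:

```text
metric comparisons (high vs low, Mann-Whitney + BH):
  volume_cc          20.86 vs   15.62   p = 0.1093  (adj 0.1640)
  median_rcbv         1.02 vs    1.28   p = 0.0000  (adj 0.0000)
  median_mtr_asym     2.36 vs    2.10   p = 0.0014  (adj 0.0029)
  median_qt2        114.77 vs  100.95   p = 0.0000  (adj 0.0000)
location tests (Fisher + BH):
  location_frontal     p = 0.0209  (adj 0.1044)
  location_temporal    p = 0.0464  (adj 0.1160)
k-means concordance with the 1240 µm²/s threshold: 1.000
```

High-ADC_L lesions show lower rCBV, higher MTR_asym and longer qT2;
the nominally significant location differences do not survive the
Benjamini-Hochberg correction over the five-location family.

## Command line

```sh
gbmphen simulate --seed 0 --n-lesions 2 --out sim/     # NIfTI bundles + ground_truth.csv
gbmphen maps adc --b0 dwi_b0.nii.gz --b1000 dwi_b1000.nii.gz --out adc.nii.gz
gbmphen maps rcbv --dsc dsc.nii.gz --meta dsc.json --brain brain.nii.gz --out rcbv.nii.gz
gbmphen maps cest --series cest.nii.gz --meta cest.json --s0 cest_s0.nii.gz \
        --brain brain.nii.gz --out-prefix lesion
gbmphen phenotype --adc adc.nii.gz --tumor tumor.nii.gz --out profile.json
gbmphen stats --cohort cohort.csv --out report.json
gbmphen run --seed 0 --out-dir results/                # simulate + full pipeline
```

4D series carry JSON sidecars for the time axis (`tr_s`, `te_s`,
`baseline_idx`), ppm offsets, or echo times.

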