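# Methods

`gbmphen` quantifies multiparametric MRI of post-chemoradiation,
IDH-wildtype glioblastoma and stratifies contrast-enhancing (CE) lesions
by their diffusion phenotype.  This note documents the models, the
defaults and their rationale, what the synthetic cohort does and does
not emulate, and the numerical choices that matter.

## The phenotyping statistic: ADC_L

Water diffusivity inside CE tumor is bimodal: a lower mode attributed to
densely cellular tumor and a higher mode to edema/necrosis.  The ADC
histogram over the tumor mask is modelled as a two-component Gaussian
mixture

    f(x) = w_lo · N(x; µ_lo, σ_lo²) + (1 − w_lo) · N(x; µ_hi, σ_hi²),

and ADC_L ≡ µ_lo, the mean of the lower component.  Lesions with
ADC_L ≥ 1240 µm²/s are labelled *high-ADC_L* (the phenotype previously
associated with favorable anti-VEGF response), below that *low-ADC_L*;
the boundary is inclusive to high.

Fitting is bounded nonlinear least squares on the density-normalized
histogram (range 0–4000 µm²/s, 50 µm²/s bins), initialized at the
25th/75th percentiles, with µ_lo ≤ µ_hi enforced by swapping.  An
expectation-maximization fit on the raw values (`method="em"`) is
available and agrees within ~30 µm²/s on well-separated mixtures.

**Degenerate fits.**  An effectively unimodal histogram can be
decomposed into two strongly overlapping Gaussians with near-zero
residual, so separation/weight thresholds alone cannot detect
unimodality.  The fit therefore collapses to a single Gaussian
(`collapsed_to_single`, ADC_L = its mean) when any of: µ_hi − µ_lo
< 100 µm²/s; min(w) < 0.02; or the single-Gaussian refit achieves
rss < 1.5 × the two-Gaussian rss (parsimony rule).

## Per-voxel maps

All maps live on one common grid (exact shape/spacing match, no
resampling): the pipeline assumes inputs were co-registered to the
post-contrast T1-weighted image beforehand.

**ADC** (µm²/s): from the two-b-value pair, ADC = ln(S₀/S₁₀₀₀)/Δb ×10⁶.
Voxels with nonpositive signal or S₁₀₀₀ > S₀ get NaN rather than a
clamped value, so ROI medians are not dragged by invalid voxels.

**deltaT1**: each T1w image is divided by its median within the brain
mask, then post − pre.  The normalization scheme before subtraction is
a configurable choice; the brain-median divisor is scale-free and
robust, and makes deltaT1 invariant to independent global rescaling of
either image.

**rCBV**: DSC signal → ΔR2*(t) = −ln(S/S̄_baseline)/TE, then the
bidirectional leakage model

    ΔR2*_meas(t) = k1·x̄(t) − k2·∫₀ᵗ x̄(τ)·e^(−kep·(t−τ)) dτ

with x̄ the mean curve of non-enhancing brain (voxels with deltaT1
below the brain median when a deltaT1 map is supplied, otherwise brain
minus tumor).  For each kep on a 21-point grid (0 plus 20 log-spaced
values up to 0.1 s⁻¹) the model is linear in (k1, k2) and solved by
exact least squares; the minimum-rss grid point wins.  This keeps the
fit deterministic, and the discrete convolution operator (recursive
trapezoid) is shared verbatim with the forward simulator, so noiseless
recovery is exact on-grid.  rCBV is the trapezoidal time-integral of
the corrected curve (measured + k2·convolution), divided by its median
over the brain mask — the output brain median is exactly 1 by
construction.  No arterial-input deconvolution is attempted.

**MTR_asym @ 3 ppm** (%): z-spectra are normalized by the unsaturated
S0.  B0 correction: k-means (default 4 clusters, fitted on a seeded
20 000-voxel subsample, then all voxels labelled) on the normalized
spectrum vectors; each cluster centroid is fitted with a single-pool
Lorentzian dip 1 − A·(Γ/2)²/((Γ/2)² + (ω − ΔB0)²) over |ω| ≤ 1.5 ppm;
every voxel inherits its cluster's ΔB0 (per-voxel refinement is
deliberately omitted — the cluster-level estimate is what the
correction scheme describes, and it is fast and testable).  Spectra are
resampled onto the nominal offsets after undoing the shift (cubic
interpolation, edge-clamped).  MTR_asym is the arithmetic mean of
[S(−ω) − S(+ω)]/S0 over sampled offsets ω ∈ [2.8, 3.2] ppm, ×100; with
dense symmetric sampling this equals the 0.4-ppm-band integral to first
order.  Voxels with |ΔB0| > 0.3 ppm are flagged; a lesion whose tumor
mask is > 25% flagged has its MTR_asym median marked invalid (the
fraction is a package choice).

**qT2 / qT2*** (ms): the 4-echo SAGE signal model is

    gradient regime:  S(τ) = S0_I · e^(−τ·R2*)
    spin regime:      S(τ) = S0_II · e^(−TE_SE·(R2*−R2)) · e^(−τ·(2R2−R2*))

with the mixed echo treated as a spin-regime sample at τ₃ < TE_SE.
Four echoes determine the four unknowns exactly, so the closed form
(R2* from the gradient pair, 2R2 − R2* from the spin pair) is the
default and interpolates the data; a nonlinear refinement flag exists
for interface compatibility but cannot improve an exactly-determined
fit.  qT2 ≥ qT2* is *not* enforced: noise may invert the ordering and
clamping would bias medians.  Default echo times (14, 34, 60, 92) ms
with TE_SE = 92 ms are representative SAGE-EPI values and
config-overridable.

**RANO measurability** is operationalized as the mask's axis-aligned
bounding box spanning ≥ 10 mm on all three axes — a simplification of
perpendicular-diameter measurement that is exact for the generator's
axis-aligned ellipsoids.

## Cohort statistics

Group comparisons use the two-sided Mann-Whitney U test (exact
enumeration when both n ≤ 8, else the tie/continuity-corrected normal
approximation); a Shapiro-Wilk gate is computed and logged but the
pipeline always stays nonparametric.  Categorical covariates and
locations use two-sided Fisher's exact tests (point-probability
convention, the sum of all table probabilities no larger than the
observed table's).  Benjamini-Hochberg correction is applied within
two families: the six MRI-metric comparisons, and the five location
tests (five categories: frontal, temporal, parietal, occipital,
other).  MTR_asym is additionally regressed on the phenotype indicator
with qT2 as covariate (OLS, complete cases, zero-variance covariates
dropped with a warning).  k = 2 k-means on z-scored (ADC_L, rCBV,
MTR_asym) — ADC_L continuous, equal weight — uses 50 restarts at a
fixed seed; cluster 1 is relabelled to the higher-mean-ADC_L cluster
and concordance against the threshold groups is reported.  Missing
values are handled per analysis by listwise deletion, never imputed.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:
87 lesions (37 high / 50 low by ground truth), ellipsoidal CE tumors
inside an ellipsoidal "brain" (semi-axes 38×38×34 mm on a 96³ 1 mm
grid), per-voxel ADC drawn from group-dependent two-Gaussian mixtures
(lower modes kept ≥ 100 µm²/s away from the cutoff so ground-truth
phenotypes are unambiguous), ROI-median targets for rCBV (1.02/1.28),
MTR_asym (2.36/2.10 %), qT2 (114.8/100.9 ms), log-normal volumes
(medians 21.4/16.4 cc, truncated to [2, 70] cc so lesions stay
RANO-measurable and inside the phantom), location/sex/MGMT/EGFR
counts allocated exactly and shuffled by seed, and negative controls
(qT2*, deltaT1, steroid dose) with no group difference.  Raw signals
are produced by forward models that the pipeline inverts: mono-
exponential DWI, gamma-variate DSC boluses with the bidirectional
leakage term, two-pool Lorentzian z-spectra (water + amine at +3 ppm,
amine amplitude solved analytically from the target asymmetry) over
spatially smooth B0 fields (RMS 0.02–0.05 ppm per lesion), and the
piecewise SAGE equations.  Noise is additive Gaussian on magnitude
signals (SNRs: DWI 50, DSC 50, CEST 100, SAGE 100, T1w 80) — a
reasonable approximation above the Rician regime.

Two deliberate devices:

- **Stratified sampling.**  Continuous per-lesion parameters are drawn
  by stratified (quasi-random) quantiles within each group, so realized
  group medians sit on the configured targets instead of wandering with
  the seed.  The `CohortConfig.null()` preset — identical group
  distributions — switches to plain i.i.d. sampling so that rank-test
  calibration experiments see genuinely exchangeable samples.
- **Normalization-consistent rCBV truth.**  The phantom brain is small
  (~230 cc), so a large tumor would shift the whole-brain median that
  defines normalized rCBV — an artifact of phantom size, not of the
  method.  The generator rescales the background so its truth field has
  brain median exactly 1, as in a full-size brain where the lesion share
  is ~1%.

What the generator does **not** emulate: anatomy (no tissue classes,
skull, vasculature), registration/motion errors, saturation-transfer
physics (z-spectra are phenomenological Lorentzians, not
Bloch-McConnell), Rician noise floors, arterial-input variability, or
scanner-specific artifacts.  Passing end-to-end tests therefore shows
that the pipeline's estimators invert the stated signal models at
realistic noise, and that the statistical battery behaves correctly on
tables with this cohort structure — not that the pipeline is robust to
real-world acquisition artifacts.

## Problem sizes and determinism

The default end-to-end cohort (87 lesions, 96³ grid, ~230 000 brain
voxels per lesion, 60 DSC frames, 37 CEST offsets, 4 echoes) runs in
roughly 8 minutes on one CPU; signals are float32 and processing is
restricted to the brain mask.  Every stochastic step (generator,
k-means subsampling, clustering restarts) is driven by explicit seeds;
a rerun with the same configuration is deterministic.  Degenerate
inputs (empty masks, zero medians, all-zero reference curves, fewer
voxels than clusters, constant samples) raise typed errors or return
flagged NaNs rather than silently propagating.

## Known limitations

- The leakage fit returns the best grid point; kep is only resolved to
  grid resolution (integral bias < 0.5% in practice).
- Cluster-level ΔB0 quantizes a smooth field; residual shifts of
  ~0.01 ppm leave MTR_asym biases well under the 5% tolerance at the
  default field amplitudes, but stronger inhomogeneity would warrant
  more clusters or per-voxel refinement.
- The deltaT1 normalization (brain-median) is one of several schemes in
  use; absolute deltaT1 levels are therefore not comparable across
  normalization choices.
- Locations are input covariates; the package does not label anatomy
  from coordinates, and frequency maps assume masks already share a
  template grid.
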