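"""Signal-level synthetic cohort generator.

Generates an 87-lesion cohort (37 high-ADC_L / 50 low-ADC_L by ground
truth) whose statistical structure mirrors the clinical population the
analysis pipeline was built for: bimodal ADC distributions inside
ellipsoidal contrast-enhancing tumor masks, group-dependent ROI medians
of rCBV / MTR_asym @ 3 ppm / qT2, group-specific volume distributions
and location frequencies, Lorentzian z-spectra with spatially smooth B0
offset fields, gamma-variate DSC boluses with bidirectional leakage,
and 4-echo SAGE decay.  Every lesion carries its ground truth, so each
pipeline stage can be verified by forward-inverse recovery.

Continuous per-lesion parameters are drawn by stratified (quasi-random)
quantile sampling within each group, so the realized group medians sit
on the configured targets instead of wandering with the seed; the
``null()`` preset disables both stratification and every group
difference for type-I-error calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm

from .core import BinaryMask, ImageVolume
from .dsc import DscSeries, leakage_convolution
from .cest import ZSpectrumSeries, lorentzian_dip
from .sage import DEFAULT_TE_MS, SageEchoSet, sage_forward
from .scalar_maps import DwiPair
from .errors import ConfigError

log = logging.getLogger(__name__)

__all__ = [
    "GroupParams",
    "CohortConfig",
    "LesionBundle",
    "default_offsets_ppm",
    "generate_truth_table",
    "generate_cohort",
    "simulate_lesion",
    "simulate_dwi",
    "simulate_zspectra",
    "simulate_sage",
    "simulate_dsc",
    "smooth_field",
]


def default_offsets_ppm() -> np.ndarray:
    """Saturation offsets sampled heavily near ±3.0 and 0 ppm."""
    pos = np.concatenate([
        np.arange(0.125, 1.001, 0.125),  # water flank
        [1.5, 2.0, 2.4],
        np.arange(2.8, 3.201, 0.1),  # amine band
        [3.5, 4.0],
    ])
    return np.concatenate([-pos[::-1], [0.0], pos])


@dataclass
class GroupParams:
    """Per-phenotype-group generator parameters.

    The lower ADC mode (``mu_lo``) is kept at least ``cutoff_margin``
    µm²/s away from the 1240 µm²/s threshold so that ground-truth
    phenotypes are unambiguous.  ROI-median targets carry the units of
    the corresponding map.
    """

    n: int
    # ADC mixture: lesion-level mu_lo ~ truncated N(mu_lo_center, mu_lo_sd)
    mu_lo_center: float
    mu_lo_sd: float
    mu_lo_bounds: tuple[float, float]
    mu_gap_range: tuple[float, float] = (450.0, 800.0)  # mu_hi − mu_lo
    sigma_lo_range: tuple[float, float] = (120.0, 180.0)
    sigma_hi_range: tuple[float, float] = (200.0, 300.0)
    w_lo_range: tuple[float, float] = (0.35, 0.65)
    # ROI-median targets
    rcbv_median: float = 1.0
    mtr_median_pct: float = 2.0
    qt2_median_ms: float = 100.0
    qt2star_median_ms: float = 60.0
    deltat1_median: float = 0.35
    # lesion volume (cc): log-normal, truncated
    volume_median_cc: float = 20.0
    volume_sigma_log: float = 0.8
    volume_bounds_cc: tuple[float, float] = (2.0, 70.0)
    # categorical covariates: exact counts (deterministic allocation,
    # shuffled by seed)
    location_counts: dict[str, int] = field(default_factory=dict)
    sex_counts: dict[str, int] = field(default_factory=dict)
    mgmt_counts: dict[str, int] = field(default_factory=dict)
    egfr_counts: dict[str, int] = field(default_factory=dict)


def _default_high() -> GroupParams:
    return GroupParams(
        n=37,
        mu_lo_center=1480.0, mu_lo_sd=90.0, mu_lo_bounds=(1360.0, 1800.0),
        rcbv_median=1.02, mtr_median_pct=2.36, qt2_median_ms=114.8,
        volume_median_cc=21.4, volume_sigma_log=0.70,
        location_counts={"frontal": 7, "temporal": 13, "parietal": 12,
                         "occipital": 3, "other": 2},
        sex_counts={"male": 25, "female": 12},
        mgmt_counts={"methylated": 13, "unmethylated": 20, "unknown": 4},
        egfr_counts={"amplified": 16, "non_amplified": 15, "unknown": 6},
    )


def _default_low() -> GroupParams:
    return GroupParams(
        n=50,
        mu_lo_center=1020.0, mu_lo_sd=90.0, mu_lo_bounds=(850.0, 1140.0),
        rcbv_median=1.28, mtr_median_pct=2.10, qt2_median_ms=100.9,
        volume_median_cc=16.4, volume_sigma_log=0.85,
        location_counts={"frontal": 22, "temporal": 8, "parietal": 12,
                         "occipital": 5, "other": 3},
        sex_counts={"male": 28, "female": 22},
        mgmt_counts={"methylated": 19, "unmethylated": 30, "unknown": 1},
        egfr_counts={"amplified": 25, "non_amplified": 21, "unknown": 4},
    )


@dataclass
class CohortConfig:
    """Full generator configuration; defaults emulate a reference
    post-chemoradiation glioblastoma cohort."""

    high: GroupParams = field(default_factory=_default_high)
    low: GroupParams = field(default_factory=_default_low)
    cutoff: float = 1240.0  # µm²/s
    seed: int = 0
    stratified: bool = True  # quasi-random per-lesion parameter sampling

    # geometry: 96³ common grid at 1 mm isotropic with an ellipsoidal brain
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_semiaxes_mm: tuple[float, float, float] = (38.0, 38.0, 34.0)

    # noise (SNR of the baseline magnitude signal; additive Gaussian)
    snr_dwi: float = 50.0
    snr_dsc: float = 50.0
    snr_cest: float = 100.0
    snr_sage: float = 100.0
    snr_t1w: float = 80.0

    # DSC acquisition / bolus
    dsc_tr_s: float = 1.5
    dsc_te_s: float = 0.030
    dsc_n_frames: int = 60
    dsc_baseline_frames: int = 10
    dsc_bolus_peak: float = 8.0  # peak ΔR2* of the reference bolus, 1/s
    dsc_bolus_alpha: float = 3.0
    dsc_bolus_tp_s: float = 6.0
    kep_range: tuple[float, float] = (0.005, 0.06)  # 1/s, per lesion
    k2_range: tuple[float, float] = (0.01, 0.05)  # 1/s, per tumor voxel

    # CEST
    offsets_ppm: np.ndarray = field(default_factory=default_offsets_ppm)
    water_amplitude: float = 0.82
    water_fwhm_ppm: float = 1.4
    amine_fwhm_ppm: float = 1.0
    b0_rms_range_ppm: tuple[float, float] = (0.02, 0.05)
    cest_band_halfwidth: float = 0.2

    # SAGE
    sage_te_ms: tuple[float, float, float, float] = DEFAULT_TE_MS

    s0_level: float = 800.0

    def __post_init__(self) -> None:
        for name, grp in (("high", self.high), ("low", self.low)):
            if grp.n < 0:
                raise ConfigError(f"{name}.n must be >= 0")
            if grp.n > 0 and grp.location_counts and sum(grp.location_counts.values()) != grp.n:
                raise ConfigError(f"{name} location counts must sum to n={grp.n}")
            for label, med in (("rcbv", grp.rcbv_median), ("mtr", grp.mtr_median_pct),
                               ("qt2", grp.qt2_median_ms), ("volume", grp.volume_median_cc)):
                if med <= 0:
                    raise ConfigError(f"{name}.{label} median must be positive")
            hist_hi = 4000.0
            if grp.mu_lo_bounds[1] + grp.mu_gap_range[1] > hist_hi:
                raise ConfigError(f"{name}: upper ADC mode exceeds the histogram range")
        if self.high.n + self.low.n == 0:
            raise ConfigError("cohort is empty")
        for snr in (self.snr_dwi, self.snr_dsc, self.snr_cest, self.snr_sage, self.snr_t1w):
            if snr is not None and snr <= 0:
                raise ConfigError("SNR values must be positive (or None for noiseless)")

    @property
    def n_total(self) -> int:
        return self.high.n + self.low.n

    @classmethod
    def null(cls, n_high: int = 37, n_low: int = 50, seed: int = 0) -> "CohortConfig":
        """A no-group-difference preset for type-I-error calibration.

        Both groups share the low-group parameter set (only the label
        differs) and per-lesion parameters are drawn i.i.d. (not
        stratified), so group tests see exchangeable samples.
        """
        base = _default_low()
        hi = replace(base, n=n_high, location_counts={}, sex_counts={},
                     mgmt_counts={}, egfr_counts={})
        lo = replace(base, n=n_low, location_counts={}, sex_counts={},
                     mgmt_counts={}, egfr_counts={})
        return cls(high=hi, low=lo, seed=seed, stratified=False)


@dataclass
class LesionBundle:
    """All raw inputs for one lesion, as the pipeline expects them."""

    lesion_id: str
    brain: BinaryMask
    tumor: BinaryMask
    dwi: DwiPair
    dsc: DscSeries
    zspectra: ZSpectrumSeries
    sage: SageEchoSet
    t1w_pre: ImageVolume
    t1w_post: ImageVolume
    clinical: dict


# ---------------------------------------------------------------------------
# per-lesion parameter sampling


def _stratified_u(n: int, rng: np.random.Generator, stratified: bool) -> np.ndarray:
    if not stratified or n == 0:
        return rng.uniform(0.0, 1.0, n)
    u = (np.arange(n) + rng.uniform(0.0, 1.0, n)) / n
    return rng.permutation(u)


def _trunc_normal(u: np.ndarray, loc: float, sd: float, bounds: tuple[float, float]) -> np.ndarray:
    a, b = (bounds[0] - loc) / sd, (bounds[1] - loc) / sd
    return truncnorm.ppf(u, a, b, loc=loc, scale=sd)


def _lognormal_median(u: np.ndarray, median: float, sigma_log: float,
                      bounds: tuple[float, float] | None = None) -> np.ndarray:
    if bounds is None:
        from scipy.stats import norm
        return median * np.exp(sigma_log * norm.ppf(u))
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    z = _trunc_normal(u, np.log(median), sigma_log, (lo, hi))
    return np.exp(z)


def _categorical(counts: dict[str, int], n: int, rng: np.random.Generator,
                 fallback: str = "unknown") -> np.ndarray:
    if not counts:
        return np.array([fallback] * n, dtype=object)
    labels = np.concatenate([[k] * v for k, v in counts.items()])
    return rng.permutation(labels)


def generate_truth_table(config: CohortConfig) -> "pd.DataFrame":
    """Per-lesion ground-truth parameters for the whole cohort.

    Deterministic for a given config (the seed drives all sampling).
    This table is also the cheap cohort surrogate for statistical
    calibration experiments that do not need voxel data.
    """
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    rows = []
    for group_name, grp in (("high", config.high), ("low", config.low)):
        n = grp.n
        if n == 0:
            continue
        s = config.stratified
        mu_lo = _trunc_normal(_stratified_u(n, rng, s), grp.mu_lo_center,
                              grp.mu_lo_sd, grp.mu_lo_bounds)
        gap = grp.mu_gap_range[0] + _stratified_u(n, rng, s) * np.ptp(grp.mu_gap_range)
        sigma_lo = grp.sigma_lo_range[0] + _stratified_u(n, rng, s) * np.ptp(grp.sigma_lo_range)
        sigma_hi = grp.sigma_hi_range[0] + _stratified_u(n, rng, s) * np.ptp(grp.sigma_hi_range)
        w_lo = grp.w_lo_range[0] + _stratified_u(n, rng, s) * np.ptp(grp.w_lo_range)
        rcbv = _lognormal_median(_stratified_u(n, rng, s), grp.rcbv_median, 0.12)
        from scipy.stats import norm as _norm
        mtr = grp.mtr_median_pct + 0.35 * _norm.ppf(_stratified_u(n, rng, s))
        qt2 = _lognormal_median(_stratified_u(n, rng, s), grp.qt2_median_ms, 0.08)
        qt2star = _lognormal_median(_stratified_u(n, rng, s), grp.qt2star_median_ms, 0.10)
        deltat1 = grp.deltat1_median + 0.08 * _norm.ppf(_stratified_u(n, rng, s))
        volume = _lognormal_median(_stratified_u(n, rng, s), grp.volume_median_cc,
                                   grp.volume_sigma_log, grp.volume_bounds_cc)
        steroid = _lognormal_median(_stratified_u(n, rng, s), 2.0, 0.9)
        kep = config.kep_range[0] + _stratified_u(n, rng, s) * np.ptp(config.kep_range)
        b0_rms = config.b0_rms_range_ppm[0] + _stratified_u(n, rng, s) * np.ptp(config.b0_rms_range_ppm)
        location = _categorical(grp.location_counts, n, rng)
        sex = _categorical(grp.sex_counts, n, rng)
        mgmt = _categorical(grp.mgmt_counts, n, rng)
        egfr = _categorical(grp.egfr_counts, n, rng)
        for i in range(n):
            rows.append({
                "group": group_name,
                "mu_lo": mu_lo[i], "sigma_lo": sigma_lo[i],
                "mu_hi": mu_lo[i] + gap[i], "sigma_hi": sigma_hi[i],
                "w_lo": w_lo[i],
                "rcbv_median": rcbv[i], "mtr_median_pct": np.clip(mtr[i], 0.2, None),
                "qt2_median_ms": qt2[i], "qt2star_median_ms": qt2star[i],
                "deltat1_median": deltat1[i],
                "volume_cc": volume[i],
                "steroid_dose_mg": steroid[i],
                "kep": kep[i], "b0_rms_ppm": b0_rms[i],
                "location": location[i], "sex": sex[i],
                "mgmt": mgmt[i], "egfr": egfr[i],
            })
    df = pd.DataFrame(rows)
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    df.insert(0, "lesion_id", [f"syn-{i:03d}" for i in range(len(df))])
    return df


# ---------------------------------------------------------------------------
# voxel-level geometry and fields


def smooth_field(shape: tuple[int, int, int], rms: float, rng: np.random.Generator,
                 coarse: int = 6) -> np.ndarray:
    """A spatially smooth zero-mean random field with the given RMS.

    Coarse Gaussian noise is upsampled with cubic spline interpolation,
    emulating slowly varying inhomogeneity (e.g. a B0 shim residual).
    """
    base = rng.standard_normal((coarse, coarse, coarse))
    zoom = [s / coarse for s in shape]
    f = ndimage.zoom(base, zoom, order=3)
    f = f[: shape[0], : shape[1], : shape[2]]
    f -= f.mean()
    sd = f.std()
    if sd > 0:
        f *= rms / sd
    return f


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[[slice(0, s) for s in shape]]
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _make_masks(config: CohortConfig, volume_cc: float,
                rng: np.random.Generator) -> tuple[BinaryMask, BinaryMask]:
    shape = config.grid_shape
    center = tuple((s - 1) / 2.0 for s in shape)
    brain = _ellipsoid_mask(shape, center, config.brain_semiaxes_mm)
    # semiaxes with mild anisotropy whose product hits the target volume
    s_base = (3.0 * volume_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    u1, u2 = rng.uniform(0.85, 1.2, 2)
    semis = np.array([s_base * u1, s_base * u2, s_base / (u1 * u2)])
    for attempt in range(8):
        shrink = 0.7 ** attempt
        offset = rng.uniform(-14.0, 14.0, 3) * shrink
        c = tuple(ci + oi for ci, oi in zip(center, offset))
        tumor = _ellipsoid_mask(shape, c, semis)
        if not (tumor & ~brain).any():
            break
    else:
        tumor = _ellipsoid_mask(shape, center, semis)
        tumor &= brain
        log.warning("tumor clipped to brain (volume %.1f cc)", volume_cc)
    sp = config.spacing_mm
    return (BinaryMask(brain, sp, kind="brain"), BinaryMask(tumor, sp, kind="tumor_ce"))


def _noise(shape, sigma, rng) -> np.ndarray:
    out = rng.standard_normal(size=shape, dtype=np.float32)
    out *= sigma
    return out


# ---------------------------------------------------------------------------
# forward simulators (one per modality)


def simulate_dwi(adc_truth: ImageVolume, s0_level: float = 800.0,
                 snr: float | None = None,
                 rng: np.random.Generator | None = None,
                 support: np.ndarray | None = None) -> DwiPair:
    """DWI pair from a ground-truth ADC map (µm²/s).

    S(b=1000) = S(0)·exp(−b·ADC·10⁻⁶); Gaussian noise of s.d.
    s0_level/snr is added to both images (``snr=None`` → noiseless).
    Voxels outside ``support`` are zero signal.
    """
    if snr is not None and snr <= 0:
        raise ConfigError("snr must be positive or None")
    adc = np.asarray(adc_truth.data, dtype=np.float64)
    sup = np.ones(adc.shape, dtype=bool) if support is None else support
    s0 = np.where(sup, s0_level, 0.0)
    s1 = np.where(sup, s0_level * np.exp(-1000.0 * adc * 1e-6), 0.0)
    if snr is not None:
        rng = rng or np.random.default_rng()
        sigma = s0_level / snr
        s0 = s0 + np.where(sup, _noise(adc.shape, sigma, rng), 0.0)
        s1 = s1 + np.where(sup, _noise(adc.shape, sigma, rng), 0.0)
    sp, fid = adc_truth.spacing, adc_truth.frame_id
    return DwiPair(
        s_b0=ImageVolume(s0, sp, fid), s_b1000=ImageVolume(s1, sp, fid),
        b_low=0.0, b_high=1000.0,
    )


def amine_band_gain(offsets_ppm: np.ndarray, amine_fwhm: float,
                    band_center: float = 3.0, band_halfwidth: float = 0.2) -> float:
    """Band-mean asymmetry produced by a unit-amplitude amine pool.

    MTR_asym is linear in the amine dip amplitude; this gain converts a
    target asymmetry (fraction of S0) into the amplitude to synthesize.
    """
    offsets_ppm = np.asarray(offsets_ppm)
    band = (offsets_ppm >= band_center - band_halfwidth) & (offsets_ppm <= band_center + band_halfwidth)
    w = offsets_ppm[band]
    la_pos = 1.0 - lorentzian_dip(w, 1.0, amine_fwhm, band_center)
    la_neg = 1.0 - lorentzian_dip(-w, 1.0, amine_fwhm, band_center)
    return float(np.mean(la_pos - la_neg))


def simulate_zspectra(mtr_target: ImageVolume, b0_field: ImageVolume,
                      offsets_ppm: np.ndarray | None = None,
                      s0_level: float = 800.0, snr: float | None = None,
                      rng: np.random.Generator | None = None,
                      support: np.ndarray | None = None,
                      water_amplitude: float = 0.82,
                      water_fwhm: float = 1.4,
                      amine_fwhm: float = 1.0,
                      band_halfwidth: float = 0.2) -> ZSpectrumSeries:
    """Two-pool Lorentzian z-spectra realizing a target MTR_asym map (%).

    The water pool sits at the voxel's ΔB0 and the amine pool at
    ΔB0 + 3 ppm; the amine amplitude is solved analytically so the
    band-averaged asymmetry of the (B0-corrected) spectrum equals the
    target.  Negative targets are rejected.
    """
    if offsets_ppm is None:
        offsets_ppm = default_offsets_ppm()
    offsets_ppm = np.asarray(offsets_ppm, dtype=np.float64)
    target = np.asarray(mtr_target.data, dtype=np.float64)
    if np.nanmin(target) < 0:
        raise ConfigError("MTR_asym targets must be nonnegative")
    if snr is not None and snr <= 0:
        raise ConfigError("snr must be positive or None")
    gain = amine_band_gain(offsets_ppm, amine_fwhm, 3.0, band_halfwidth)
    amp = target / 100.0 / gain
    delta = np.asarray(b0_field.data, dtype=np.float64)
    sup = np.ones(target.shape, dtype=bool) if support is None else support

    shape4 = target.shape + (offsets_ppm.size,)
    signal = np.zeros(shape4, dtype=np.float32)
    w = offsets_ppm[None, :]
    d = delta[sup][:, None]
    a = amp[sup][:, None]
    hw_w = (water_fwhm / 2.0) ** 2
    hw_a = (amine_fwhm / 2.0) ** 2
    z = (1.0
         - water_amplitude * hw_w / (hw_w + (w - d) ** 2)
         - a * hw_a / (hw_a + (w - d - 3.0) ** 2))
    signal[sup, :] = (s0_level * z).astype(np.float32)
    s0 = np.where(sup, s0_level, 0.0)
    if snr is not None:
        rng = rng or np.random.default_rng()
        sigma = s0_level / snr
        signal[sup, :] += _noise((int(sup.sum()), offsets_ppm.size), sigma, rng)
        s0 = s0 + np.where(sup, _noise(target.shape, sigma, rng), 0.0)
    return ZSpectrumSeries(
        signal=signal, offsets_ppm=offsets_ppm,
        s0=ImageVolume(s0, mtr_target.spacing, mtr_target.frame_id),
        frame_id=mtr_target.frame_id,
    )


def simulate_sage(qt2_truth: ImageVolume, qt2star_truth: ImageVolume,
                  te_ms: tuple[float, float, float, float] = DEFAULT_TE_MS,
                  s0_level: float = 800.0, snr: float | None = None,
                  rng: np.random.Generator | None = None,
                  support: np.ndarray | None = None) -> SageEchoSet:
    """4-echo SAGE set from ground-truth T2/T2* maps (ms).

    Voxels with T2* > T2 are physically unusual but generated as-is
    (with a logged warning); the solver flags them downstream.
    """
    if snr is not None and snr <= 0:
        raise ConfigError("snr must be positive or None")
    t2 = np.asarray(qt2_truth.data, dtype=np.float64)
    t2s = np.asarray(qt2star_truth.data, dtype=np.float64)
    n_odd = int((t2s > t2).sum())
    if n_odd:
        log.warning("simulate_sage: %d voxels with T2* > T2", n_odd)
    sup = np.ones(t2.shape, dtype=bool) if support is None else support
    s0 = np.where(sup, s0_level, 0.0)
    echoes_data = sage_forward(s0, s0, t2, t2s, te_ms)
    if snr is not None:
        rng = rng or np.random.default_rng()
        sigma = s0_level / snr
        echoes_data = [e + np.where(sup, _noise(t2.shape, sigma, rng), 0.0)
                       for e in echoes_data]
    sp, fid = qt2_truth.spacing, qt2_truth.frame_id
    return SageEchoSet(
        echoes=[ImageVolume(e, sp, fid) for e in echoes_data],
        te_ms=tuple(te_ms),
    )


def gamma_variate_bolus(t: np.ndarray, t0: float, peak: float,
                        alpha: float, tp: float) -> np.ndarray:
    """Gamma-variate ΔR2* bolus peaking at ``peak`` 1/s, ``tp`` s after arrival."""
    s = np.maximum(t - t0, 0.0) / tp
    with np.errstate(invalid="ignore"):
        x = peak * s ** alpha * np.exp(alpha * (1.0 - s))
    return np.where(t > t0, x, 0.0)


def simulate_dsc(rcbv_truth: ImageVolume, k2_field: ImageVolume, kep: float,
                 config: CohortConfig | None = None,
                 snr: float | None = None,
                 rng: np.random.Generator | None = None,
                 support: np.ndarray | None = None) -> DscSeries:
    """DSC signal series with bidirectional leakage.

    Each voxel's curve is ΔR2*(t) = rCBV_truth·x̄(t) − k2·∫x̄·e^(−kep·)
    with a gamma-variate reference bolus x̄; the discrete convolution is
    the same operator the fit inverts.  Signals are
    S(t) = S0·exp(−TE·ΔR2*) plus optional Gaussian noise.
    """
    cfg = config or CohortConfig()
    if snr is not None and snr <= 0:
        raise ConfigError("snr must be positive or None")
    t = np.arange(cfg.dsc_n_frames) * cfg.dsc_tr_s
    t0 = cfg.dsc_baseline_frames * cfg.dsc_tr_s
    xbar = gamma_variate_bolus(t, t0, cfg.dsc_bolus_peak, cfg.dsc_bolus_alpha, cfg.dsc_bolus_tp_s)
    conv = leakage_convolution(xbar, t, float(kep))
    truth = np.asarray(rcbv_truth.data)
    k2 = np.asarray(k2_field.data)
    sup = np.ones(truth.shape, dtype=bool) if support is None else support
    signal = np.zeros(truth.shape + (t.size,), dtype=np.float32)
    xbar32 = xbar.astype(np.float32)
    conv32 = conv.astype(np.float32)
    curves = truth[sup].astype(np.float32)[:, None] * xbar32[None, :] \
        - k2[sup].astype(np.float32)[:, None] * conv32[None, :]
    curves *= np.float32(-cfg.dsc_te_s)
    np.exp(curves, out=curves)
    curves *= np.float32(cfg.s0_level)
    signal[sup, :] = curves
    if snr is not None:
        rng = rng or np.random.default_rng()
        sigma = cfg.s0_level / snr
        signal[sup, :] += _noise((int(sup.sum()), t.size), sigma, rng)
    return DscSeries(
        signal=signal, tr=cfg.dsc_tr_s, te=cfg.dsc_te_s,
        baseline_idx=np.arange(cfg.dsc_baseline_frames),
        spacing=rcbv_truth.spacing, frame_id=rcbv_truth.frame_id,
    )


# ---------------------------------------------------------------------------
# lesion and cohort assembly


def simulate_lesion(truth: dict, config: CohortConfig, lesion_index: int) -> LesionBundle:
    """Build one lesion's raw data bundle from its ground-truth row."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1 + lesion_index]))
    sp = config.spacing_mm
    brain, tumor = _make_masks(config, float(truth["volume_cc"]), rng)
    b = brain.data
    tm = tumor.data
    shape = config.grid_shape
    fid = str(truth["lesion_id"])

    # ground-truth voxel fields
    adc = np.full(shape, np.nan)
    adc[b] = np.clip(rng.normal(900.0, 150.0, int(b.sum())), 150.0, 3500.0)
    n_t = int(tm.sum())
    lo = rng.uniform(0.0, 1.0, n_t) < truth["w_lo"]
    draws = np.where(
        lo,
        rng.normal(truth["mu_lo"], truth["sigma_lo"], n_t),
        rng.normal(truth["mu_hi"], truth["sigma_hi"], n_t),
    )
    adc[tm] = np.clip(draws, 100.0, 3900.0)
    adc_vol = ImageVolume(np.nan_to_num(adc), sp, fid)

    rcbv = np.zeros(shape)
    rcbv[b] = np.exp(rng.normal(0.0, 0.15, int(b.sum())))
    rcbv[tm] = truth["rcbv_median"] * np.exp(rng.normal(0.0, 0.15, n_t))
    # rCBV is defined relative to the whole-brain median, and the
    # synthetic brain is small enough for the tumor to pull that median;
    # rescale the background so the truth field satisfies its own
    # normalization (brain median = 1) while the ROI median stays on
    # target, as in a full-size brain where the lesion share is tiny
    bg = b & ~tm
    for _ in range(4):
        m = np.median(rcbv[b])
        if abs(m - 1.0) < 1e-6:
            break
        rcbv[bg] /= m
    k2 = np.zeros(shape)
    k2[tm] = rng.uniform(*config.k2_range, n_t)

    mtr = np.zeros(shape)
    mtr[b] = np.clip(rng.normal(1.5, 0.3, int(b.sum())), 0.0, None)
    mtr[tm] = np.clip(truth["mtr_median_pct"] + rng.normal(0.0, 0.4, n_t), 0.0, None)
    b0 = smooth_field(shape, float(truth["b0_rms_ppm"]), rng)

    qt2 = np.full(shape, 85.0)
    qt2[b] = 85.0 * np.exp(rng.normal(0.0, 0.05, int(b.sum())))
    qt2[tm] = truth["qt2_median_ms"] * np.exp(rng.normal(0.0, 0.05, n_t))
    qt2s = np.full(shape, 45.0)
    qt2s[b] = 45.0 * np.exp(rng.normal(0.0, 0.08, int(b.sum())))
    qt2s[tm] = truth["qt2star_median_ms"] * np.exp(rng.normal(0.0, 0.08, n_t))

    pre = np.zeros(shape)
    pre[b] = 600.0 * (1.0 + rng.normal(0.0, 0.05, int(b.sum())))
    post = pre.copy()
    post[tm] = pre[tm] + 600.0 * (truth["deltat1_median"] + rng.normal(0.0, 0.08, n_t))
    if config.snr_t1w is not None:
        sigma = 600.0 / config.snr_t1w
        pre[b] += rng.normal(0.0, sigma, int(b.sum()))
        post[b] += rng.normal(0.0, sigma, int(b.sum()))

    dwi = simulate_dwi(adc_vol, config.s0_level, config.snr_dwi, rng, support=b)
    dsc = simulate_dsc(ImageVolume(rcbv, sp, fid), ImageVolume(k2, sp, fid),
                       float(truth["kep"]), config, config.snr_dsc, rng, support=b)
    zsp = simulate_zspectra(ImageVolume(mtr, sp, fid), ImageVolume(b0, sp, fid),
                            config.offsets_ppm, config.s0_level, config.snr_cest,
                            rng, support=b,
                            water_amplitude=config.water_amplitude,
                            water_fwhm=config.water_fwhm_ppm,
                            amine_fwhm=config.amine_fwhm_ppm,
                            band_halfwidth=config.cest_band_halfwidth)
    sage = simulate_sage(ImageVolume(qt2, sp, fid), ImageVolume(qt2s, sp, fid),
                         config.sage_te_ms, config.s0_level, config.snr_sage,
                         rng, support=b)

    clinical = {k: truth[k] for k in ("location", "sex", "mgmt", "egfr", "steroid_dose_mg")}
    return LesionBundle(
        lesion_id=fid, brain=brain, tumor=tumor, dwi=dwi, dsc=dsc,
        zspectra=zsp, sage=sage,
        t1w_pre=ImageVolume(pre, sp, fid), t1w_post=ImageVolume(post, sp, fid),
        clinical=clinical,
    )


def generate_cohort(config: CohortConfig | None = None) -> Iterator[tuple[LesionBundle, dict]]:
    """Yield (bundle, ground-truth row) for every lesion in the cohort.

    Lazy by design: each bundle holds several 4D arrays, so callers
    should process and discard lesions one at a time.
    """
    cfg = config or CohortConfig()
    truth = generate_truth_table(cfg)
    for i, row in truth.iterrows():
        yield simulate_lesion(row.to_dict(), cfg, int(i)), row.to_dict()
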