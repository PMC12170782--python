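"""Amine CEST z-spectrum processing.

Static-field (B0) inhomogeneity shifts every voxel's z-spectrum along
the frequency axis.  The correction clusters normalized z-spectra with
k-means, fits a single-pool Lorentzian dip to each cluster centroid near
the water resonance to estimate the cluster's frequency offset ΔB0, and
re-interpolates each voxel's spectrum onto the nominal offsets after
undoing its cluster's shift.  MTR_asym at the amine resonance is then
the band-averaged asymmetry [S(−ω) − S(+ω)]/S0 for ω ∈ 3.0 ± 0.2 ppm,
expressed in percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import interp1d
from scipy.optimize import curve_fit
from sklearn.cluster import KMeans

from .core import BinaryMask, ImageVolume, check_same_grid
from .errors import ClusteringError, ParameterError

log = logging.getLogger(__name__)

__all__ = [
    "ZSpectrumSeries",
    "LorentzianFit",
    "B0Map",
    "lorentzian_dip",
    "cluster_zspectra",
    "estimate_b0",
    "correct_b0",
    "compute_mtr_asym",
    "lesion_b0_exclusion",
]

B0_FLAG_THRESHOLD_PPM = 0.3  # exclusion rule for excessive inhomogeneity


@dataclass
class ZSpectrumSeries:
    """Per-voxel saturation spectra over ppm offsets plus the
    unsaturated reference image S0.

    Offsets must be strictly increasing and sample each of
    [−3.2, −2.8], [2.8, 3.2] and a neighborhood of 0 with at least
    three points (the amine, reference and water resonances).
    """

    signal: np.ndarray  # (x, y, z, n_offsets)
    offsets_ppm: np.ndarray
    s0: ImageVolume
    frame_id: str | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=np.float64)
        if self.signal.ndim != 4:
            raise ParameterError(f"z-spectrum series must be 4D, got {self.signal.shape}")
        if self.signal.shape[3] != self.offsets_ppm.size:
            raise ParameterError("offset count does not match the 4th axis")
        if np.any(np.diff(self.offsets_ppm) <= 0):
            raise ParameterError("offsets_ppm must be strictly increasing")
        for lo, hi, name in [(-3.2, -2.8, "-3 ppm"), (2.8, 3.2, "+3 ppm"), (-0.5, 0.5, "water")]:
            if np.sum((self.offsets_ppm >= lo) & (self.offsets_ppm <= hi)) < 3:
                raise ParameterError(f"need >= 3 offsets in the {name} band [{lo}, {hi}]")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.s0.spacing


@dataclass
class LorentzianFit:
    """Single-pool Lorentzian dip parameters for a centroid spectrum."""

    amplitude: float  # fraction of S0
    fwhm: float  # ppm
    center: float  # ppm (= ΔB0)
    rss: float
    converged: bool = True


@dataclass
class B0Map:
    """Per-voxel static-field offset (ppm) plus the excessive-
    inhomogeneity flag mask (|ΔB0| > threshold)."""

    delta_b0: ImageVolume
    flagged: BinaryMask
    threshold_ppm: float = B0_FLAG_THRESHOLD_PPM
    cluster_fits: list[LorentzianFit] | None = None


def lorentzian_dip(omega: np.ndarray, amplitude: float, fwhm: float, center: float) -> np.ndarray:
    """Normalized z-spectrum model 1 − A·(Γ/2)² / ((Γ/2)² + (ω − c)²)."""
    hw2 = (fwhm / 2.0) ** 2
    return 1.0 - amplitude * hw2 / (hw2 + (omega - center) ** 2)


def _normalized_spectra(series: ZSpectrumSeries, mask: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    """(voxel, offset) spectra divided by S0, restricted to valid mask voxels."""
    check_same_grid(series.s0, mask)
    s0 = series.s0.data
    sel = mask.data & (s0 > 0)
    spectra = series.signal[sel, :] / s0[sel, None]
    return spectra, sel


def cluster_zspectra(
    series: ZSpectrumSeries,
    mask: BinaryMask,
    n_clusters: int = 4,
    seed: int = 0,
    max_fit_voxels: int = 20000,
) -> tuple[np.ndarray, np.ndarray]:
    """k-means on S0-normalized spectrum vectors.

    Returns ``labels`` (3D int array, −1 outside the mask) and the
    centroid spectra (n_clusters, n_offsets).  For large masks the
    k-means model is fitted on a seeded subsample and then used to
    label every voxel; the run is deterministic under a fixed seed.
    """
    spectra, sel = _normalized_spectra(series, mask)
    n_vox = spectra.shape[0]
    if n_vox < n_clusters:
        raise ClusteringError(f"{n_vox} voxels < {n_clusters} clusters")
    rng = np.random.default_rng(seed)
    if n_vox > max_fit_voxels:
        idx = rng.choice(n_vox, size=max_fit_voxels, replace=False)
        fit_data = spectra[idx]
    else:
        fit_data = spectra
    km = KMeans(n_clusters=n_clusters, n_init=4, random_state=seed)
    km.fit(fit_data)
    flat_labels = km.predict(spectra)
    labels = np.full(mask.shape, -1, dtype=int)
    labels[sel] = flat_labels
    return labels, km.cluster_centers_


def _fit_centroid(offsets: np.ndarray, centroid: np.ndarray, fit_window_ppm: float,
                  max_center_ppm: float) -> LorentzianFit:
    win = np.abs(offsets) <= fit_window_ppm
    x, y = offsets[win], centroid[win]
    a0 = max(1e-3, 1.0 - float(y.min()))
    c0 = float(x[np.argmin(y)])
    try:
        popt, _ = curve_fit(
            lorentzian_dip, x, y,
            p0=[a0, 1.4, c0],
            bounds=([0.0, 0.05, -max_center_ppm], [1.5, 6.0, max_center_ppm]),
            maxfev=5000,
        )
        rss = float(np.sum((lorentzian_dip(x, *popt) - y) ** 2))
        return LorentzianFit(amplitude=float(popt[0]), fwhm=float(popt[1]),
                             center=float(popt[2]), rss=rss, converged=True)
    except RuntimeError:
        return LorentzianFit(amplitude=np.nan, fwhm=np.nan, center=np.nan,
                             rss=np.nan, converged=False)


def estimate_b0(
    centroids: np.ndarray,
    labels: np.ndarray,
    offsets_ppm: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    threshold_ppm: float = B0_FLAG_THRESHOLD_PPM,
    fit_window_ppm: float = 1.5,
    max_center_ppm: float = 1.0,
) -> B0Map:
    """ΔB0 map from per-cluster Lorentzian fits of the water dip.

    Each centroid is fitted over |ω| ≤ ``fit_window_ppm``; every voxel
    inherits its cluster's fitted center.  Voxels whose |ΔB0| exceeds
    ``threshold_ppm`` — or whose cluster fit failed — are flagged.
    """
    offsets_ppm = np.asarray(offsets_ppm, dtype=np.float64)
    fits = [_fit_centroid(offsets_ppm, c, fit_window_ppm, max_center_ppm) for c in centroids]
    delta = np.full(labels.shape, np.nan)
    flagged = np.zeros(labels.shape, dtype=bool)
    for k, fit in enumerate(fits):
        vox = labels == k
        if not fit.converged:
            log.warning("estimate_b0: cluster %d Lorentzian fit failed; voxels flagged", k)
            flagged |= vox
            continue
        delta[vox] = fit.center
        if abs(fit.center) > threshold_ppm:
            flagged |= vox
    return B0Map(
        delta_b0=ImageVolume(data=delta, spacing=spacing),
        flagged=BinaryMask(data=flagged, spacing=spacing, kind="brain"),
        threshold_ppm=threshold_ppm,
        cluster_fits=fits,
    )


def correct_b0(series: ZSpectrumSeries, b0: B0Map) -> ZSpectrumSeries:
    """Shift each voxel's spectrum by −ΔB0 and resample onto the
    nominal offsets (cubic interpolation, edge-clamped).

    Because ΔB0 is constant within a cluster, voxels sharing a value are
    corrected in one vectorized pass.
    """
    if series.signal.shape[:3] != b0.delta_b0.shape:
        raise ParameterError("B0 map grid does not match the series")
    offsets = series.offsets_ppm
    delta = b0.delta_b0.data
    out = series.signal.astype(np.float64).copy()
    values = np.unique(delta[np.isfinite(delta)])
    for d in values:
        if d == 0.0:
            continue
        vox = delta == d
        block = series.signal[vox, :]
        f = interp1d(offsets, block, kind="cubic", axis=1, bounds_error=False,
                     fill_value=(block[:, 0], block[:, -1]))
        # a dip centred at +d moves back to 0 when sampled at ω + d
        query = np.clip(offsets + d, offsets[0], offsets[-1])
        out[vox, :] = f(query)
    return ZSpectrumSeries(signal=out, offsets_ppm=offsets, s0=series.s0,
                           frame_id=series.frame_id)


def compute_mtr_asym(
    series: ZSpectrumSeries,
    band_center: float = 3.0,
    band_halfwidth: float = 0.2,
) -> ImageVolume:
    """MTR asymmetry map (%) at the amine resonance.

    Mean over sampled offsets ω ∈ [center − hw, center + hw] of
    [S(−ω) − S(+ω)]/S0, ×100.  Negative-offset samples are matched to
    the positive offsets by cubic interpolation, so asymmetric sampling
    grids are handled.  Voxels with S0 ≤ 0 are NaN.
    """
    offsets = series.offsets_ppm
    lo, hi = band_center - band_halfwidth, band_center + band_halfwidth
    band = (offsets >= lo) & (offsets <= hi)
    if band.sum() < 1:
        raise ParameterError(f"no sampled offsets in [{lo}, {hi}] ppm")
    pos_off = offsets[band]
    s_pos = series.signal[..., band].astype(np.float64)
    neg_exact = np.isin(-pos_off, offsets)
    if neg_exact.all():
        neg_idx = np.searchsorted(offsets, -pos_off)
        s_neg = series.signal[..., neg_idx].astype(np.float64)
    else:
        f = interp1d(offsets, series.signal, kind="cubic", axis=-1, bounds_error=True)
        s_neg = f(-pos_off)
    s0 = series.s0.data
    with np.errstate(divide="ignore", invalid="ignore"):
        asym = (s_neg - s_pos).mean(axis=-1) / s0 * 100.0
    asym[s0 <= 0] = np.nan
    return ImageVolume(data=asym, spacing=series.spacing, frame_id=series.frame_id)


def lesion_b0_exclusion(
    b0: B0Map,
    tumor: BinaryMask,
    max_flagged_fraction: float = 0.25,
) -> tuple[bool, float]:
    """Lesion-level quality gate for the MTR_asym median.

    Returns ``(excluded, flagged_fraction)``: the lesion's MTR_asym
    median is considered unreliable when more than
    ``max_flagged_fraction`` of its tumor voxels carry the excessive-
    inhomogeneity flag.
    """
    check_same_grid(b0.flagged, tumor)
    n = tumor.n_voxels
    if n == 0:
        return True, 1.0
    frac = float(b0.flagged.data[tumor.data].mean())
    return frac > max_flagged_fraction, frac
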