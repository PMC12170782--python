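"""DSC perfusion: signal → ΔR2*, bidirectional leakage correction, rCBV.

The measured tissue curve is modelled as

    ΔR2*_meas(t) = k1·x̄(t) − k2·∫₀ᵗ x̄(τ)·exp(−kep·(t−τ)) dτ

where x̄(t) is a whole-brain reference curve from non-enhancing tissue,
k1 scales the intravascular component, and the convolution term captures
contrast extravasation with efflux rate kep (bidirectional leakage).
For each candidate kep on a grid the model is linear in (k1, k2), so the
fit is a deterministic grid search over exact linear least squares.
rCBV is the time integral of the leakage-corrected curve, normalized to
the median rCBV of the brain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import BinaryMask, ImageVolume, check_same_grid
from .errors import FitError, NormalizationError, ParameterError

log = logging.getLogger(__name__)

__all__ = [
    "DscSeries",
    "LeakageFit",
    "default_kep_grid",
    "leakage_convolution",
    "signal_to_delta_r2star",
    "estimate_reference_curve",
    "fit_bidirectional_leakage",
    "fit_leakage_volume",
    "compute_rcbv",
]


def default_kep_grid() -> np.ndarray:
    """Efflux-rate grid: 0 plus 20 log-spaced values up to 0.1 s⁻¹."""
    return np.concatenate([[0.0], np.logspace(-3, -1, 20)])


@dataclass
class DscSeries:
    """A 4D DSC signal time series (x, y, z, t).

    ``baseline_idx`` are the pre-bolus frame indices used for the
    signal baseline S̄; they must be nonempty and the series must have
    at least 10 time points.
    """

    signal: np.ndarray
    tr: float
    te: float
    baseline_idx: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    frame_id: str | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 4:
            raise ParameterError(f"DSC series must be 4D, got shape {self.signal.shape}")
        if self.signal.shape[3] < 10:
            raise ParameterError("DSC series needs >= 10 time points")
        if self.tr <= 0:
            raise ParameterError("tr must be positive")
        if self.te <= 0:
            raise ParameterError("te must be positive")
        self.baseline_idx = np.atleast_1d(np.asarray(self.baseline_idx, dtype=int))
        if self.baseline_idx.size == 0:
            raise ParameterError("baseline_idx must be nonempty")

    @property
    def n_frames(self) -> int:
        return self.signal.shape[3]

    @property
    def time(self) -> np.ndarray:
        """Frame times in seconds."""
        return np.arange(self.n_frames) * self.tr


def signal_to_delta_r2star(series: DscSeries) -> np.ndarray:
    """ΔR2*(t) = −ln(S(t)/S̄_baseline)/TE, per voxel (1/s).

    Voxels with a nonpositive baseline are NaN over the whole curve.
    """
    sig = series.signal.astype(np.float64)
    baseline = sig[..., series.baseline_idx].mean(axis=-1)
    bad = baseline <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        dr2s = -np.log(sig / baseline[..., None]) / series.te
    dr2s[bad, :] = np.nan
    dr2s[~np.isfinite(dr2s)] = np.nan
    return dr2s


def leakage_convolution(x: np.ndarray, t: np.ndarray, kep: float) -> np.ndarray:
    """Causal convolution ∫₀ᵗ x(τ)·exp(−kep·(t−τ)) dτ on a uniform grid.

    Uses an exactly-recursive trapezoid rule, y_i = y_{i-1}·E + Δt/2·
    (x_i + x_{i-1}·E) with E = exp(−kep·Δt), so the discrete operator is
    shared verbatim between the forward simulator and the fit.
    """
    x = np.asarray(x, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    dt = t[1] - t[0]
    e = np.exp(-kep * dt)
    y = np.zeros_like(x)
    for i in range(1, x.size):
        y[i] = y[i - 1] * e + 0.5 * dt * (x[i] + x[i - 1] * e)
    return y


def estimate_reference_curve(
    dr2s: np.ndarray,
    brain: BinaryMask,
    *,
    deltat1: ImageVolume | None = None,
    exclude: BinaryMask | None = None,
) -> np.ndarray:
    """Whole-brain mean ΔR2* curve from non-enhancing tissue.

    Non-enhancing voxels are brain voxels whose deltaT1 enhancement lies
    below the brain median when a deltaT1 map is supplied; otherwise
    brain voxels outside ``exclude`` (typically the tumor mask);
    otherwise the whole brain.
    """
    sel = brain.data.copy()
    if deltat1 is not None:
        check_same_grid(deltat1, brain)
        dvals = deltat1.data[brain.data]
        med = np.nanmedian(dvals)
        sel &= deltat1.data < med
    elif exclude is not None:
        check_same_grid(exclude, brain)
        sel &= ~exclude.data
    curves = dr2s[sel, :]
    curves = curves[np.isfinite(curves).all(axis=1)]
    if curves.size == 0:
        raise FitError("no valid voxels for the reference curve")
    ref = curves.mean(axis=0)
    if np.allclose(ref, 0.0):
        raise FitError("degenerate (all-zero) reference curve")
    return ref


def _design_matrices(reference: np.ndarray, t: np.ndarray, kep_grid: np.ndarray):
    for kep in kep_grid:
        conv = leakage_convolution(reference, t, float(kep))
        yield float(kep), np.column_stack([reference, -conv]), conv


@dataclass
class LeakageFit:
    """Per-voxel bidirectional leakage model parameters."""

    k1: float
    k2: float
    kep: float
    rss: float


def fit_bidirectional_leakage(
    curve: np.ndarray,
    reference: np.ndarray,
    t: np.ndarray,
    kep_grid: np.ndarray | None = None,
) -> LeakageFit:
    """Fit one ΔR2* curve; linear least squares on (k1, k2) per grid kep."""
    if kep_grid is None:
        kep_grid = default_kep_grid()
    reference = np.asarray(reference, dtype=np.float64)
    if np.allclose(reference, 0.0):
        raise FitError("degenerate (all-zero) reference curve")
    curve = np.asarray(curve, dtype=np.float64)
    best: LeakageFit | None = None
    for kep, X, _ in _design_matrices(reference, t, np.asarray(kep_grid)):
        beta, *_ = np.linalg.lstsq(X, curve, rcond=None)
        rss = float(np.sum((curve - X @ beta) ** 2))
        if best is None or rss < best.rss:
            best = LeakageFit(k1=float(beta[0]), k2=float(beta[1]), kep=kep, rss=rss)
    assert best is not None
    return best


def fit_leakage_volume(
    curves: np.ndarray,
    reference: np.ndarray,
    t: np.ndarray,
    kep_grid: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Vectorized leakage fit for many voxels.

    ``curves`` is (n_voxels, n_frames).  Returns per-voxel arrays k1,
    k2, kep, rss and the corrected curves (measured + k2·convolution).
    """
    if kep_grid is None:
        kep_grid = default_kep_grid()
    reference = np.asarray(reference, dtype=np.float64)
    if np.allclose(reference, 0.0):
        raise FitError("degenerate (all-zero) reference curve")
    curves = np.asarray(curves)
    work_dtype = np.float32 if curves.dtype == np.float32 else np.float64
    Y = curves.T  # (T, N); kept in the caller's dtype to bound memory traffic
    n = Y.shape[1]
    kep_grid = np.asarray(kep_grid, dtype=np.float64)
    best_rss = np.full(n, np.inf)
    best_k1 = np.zeros(n)
    best_k2 = np.zeros(n)
    best_idx = np.zeros(n, dtype=int)
    conv_rows = np.empty((kep_grid.size, t.size))
    yty = np.einsum("ij,ij->j", Y, Y, dtype=np.float64)
    for i, (kep, X, conv) in enumerate(_design_matrices(reference, t, kep_grid)):
        conv_rows[i] = conv
        # normal equations: X is (T,2), identical for all voxels
        X = X.astype(work_dtype)
        XtX = (X.T @ X).astype(np.float64)
        XtY = (X.T @ Y).astype(np.float64)  # (2, N)
        try:
            beta = np.linalg.solve(XtX, XtY)
        except np.linalg.LinAlgError:
            beta = np.linalg.pinv(XtX) @ XtY
        # rss = yᵀy − 2βᵀXᵀy + βᵀXᵀXβ, avoiding the (T, N) residual
        rss = yty - 2.0 * np.einsum("ij,ij->j", beta, XtY) \
            + np.einsum("ij,ij->j", beta, XtX @ beta)
        rss = np.maximum(rss, 0.0)
        better = rss < best_rss
        best_rss[better] = rss[better]
        best_k1[better] = beta[0, better]
        best_k2[better] = beta[1, better]
        best_idx[better] = i
    corrected = curves + best_k2.astype(work_dtype)[:, None] * conv_rows.astype(work_dtype)[best_idx]
    return {
        "k1": best_k1,
        "k2": best_k2,
        "kep": kep_grid[best_idx],
        "rss": best_rss,
        "corrected": corrected,
    }


def compute_rcbv(
    series: DscSeries,
    brain: BinaryMask,
    *,
    tumor: BinaryMask | None = None,
    deltat1: ImageVolume | None = None,
    kep_grid: np.ndarray | None = None,
) -> ImageVolume:
    """Brain-median-normalized, leakage-corrected rCBV map.

    Per brain voxel the ΔR2* curve is leakage-corrected, integrated over
    the full acquisition (trapezoid), and the map is divided by its
    median over the brain mask, so the output brain median is exactly 1.
    Voxels outside the brain (or with invalid curves) are NaN.
    """
    if series.signal.shape[:3] != brain.shape:
        raise ParameterError("DSC series and brain mask shapes differ")
    t = series.time
    # ΔR2* only where needed: the full 4D transform would be pure
    # memory traffic for voxels outside the brain
    sig = series.signal[brain.data, :]
    if sig.dtype != np.float32:
        sig = sig.astype(np.float64)
    baseline = sig[:, series.baseline_idx].mean(axis=1, dtype=np.float64).astype(sig.dtype)
    good = baseline > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        curves_all = -np.log(sig / baseline[:, None]) / np.asarray(series.te, dtype=sig.dtype)
    good &= np.isfinite(curves_all).all(axis=1)
    curves = curves_all[good]
    if curves.shape[0] == 0:
        raise FitError("no valid brain voxels in the DSC series")
    # reference from non-enhancing tissue (deltaT1 below the brain
    # median if available, else outside the tumor mask)
    ref_sel = np.ones(curves.shape[0], dtype=bool)
    if deltat1 is not None:
        check_same_grid(deltat1, brain)
        dvals = deltat1.data[brain.data][good]
        ref_sel = dvals < np.nanmedian(dvals)
    elif tumor is not None:
        check_same_grid(tumor, brain)
        ref_sel = ~tumor.data[brain.data][good]
    ref = curves[ref_sel].mean(axis=0)
    if np.allclose(ref, 0.0):
        raise FitError("degenerate (all-zero) reference curve")
    fits = fit_leakage_volume(curves, ref, t, kep_grid)
    sel = brain.data.copy()
    sel[brain.data] = good
    raw = np.trapezoid(fits["corrected"], t, axis=1)
    out = np.full(brain.shape, np.nan)
    out[sel] = raw
    med = np.nanmedian(out[brain.data])
    if not np.isfinite(med) or med <= 0:
        raise NormalizationError(f"nonpositive brain-median rCBV ({med})")
    out /= med
    return ImageVolume(data=out, spacing=brain.spacing, frame_id=series.frame_id)
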