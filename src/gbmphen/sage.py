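"""Quantitative T2 and T2* maps from 4-echo spin-and-gradient-echo
(SAGE) EPI reference images.

The SAGE readout acquires two gradient echoes before, and a mixed plus
a spin echo after, the refocusing pulse.  With τ the echo time in
seconds and TE_SE the spin-echo time, the piecewise signal model is

    gradient regime:  S(τ) = S0_I  · exp(−τ·R2*)
    spin regime:      S(τ) = S0_II · exp(−TE_SE·(R2* − R2)) · exp(−τ·(2·R2 − R2*))

Four echoes determine the four unknowns (S0_I, S0_II, R2, R2*) exactly,
so the closed-form solver is the default:

    R2*        = ln(S1/S2) / (τ2 − τ1)
    2·R2 − R2* = ln(S3/S4) / (τ4 − τ3)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import BinaryMask, ImageVolume, check_same_grid, masked_values
from .errors import ParameterError

log = logging.getLogger(__name__)

__all__ = ["SageEchoSet", "DEFAULT_TE_MS", "solve_sage", "sage_forward", "roi_qt2_medians"]

# Representative SAGE-EPI echo times; override per acquisition.
DEFAULT_TE_MS: tuple[float, float, float, float] = (14.0, 34.0, 60.0, 92.0)


@dataclass
class SageEchoSet:
    """Four echo volumes ordered by echo time.

    The first two echoes are gradient echoes; the third (mixed) and
    fourth (spin) echoes follow the refocusing pulse and share the
    spin-regime signal equation.  ``te_ms[3]`` must equal ``te_se_ms``.
    """

    echoes: list[ImageVolume]
    te_ms: tuple[float, float, float, float] = DEFAULT_TE_MS
    te_se_ms: float | None = None

    def __post_init__(self) -> None:
        if len(self.echoes) != 4:
            raise ParameterError(f"SAGE needs exactly 4 echoes, got {len(self.echoes)}")
        check_same_grid(*self.echoes)
        self.te_ms = tuple(float(t) for t in self.te_ms)
        if np.any(np.diff(self.te_ms) <= 0):
            raise ParameterError(f"echo times must be strictly increasing: {self.te_ms}")
        if self.te_se_ms is None:
            self.te_se_ms = self.te_ms[3]
        if abs(self.te_se_ms - self.te_ms[3]) > 1e-9:
            raise ParameterError("the last echo must be the spin echo (te_ms[3] == te_se_ms)")

    @property
    def regime(self) -> tuple[str, str, str, str]:
        return ("gradient", "gradient", "spin", "spin")


def sage_forward(
    s0_i: np.ndarray,
    s0_ii: np.ndarray,
    t2_ms: np.ndarray,
    t2star_ms: np.ndarray,
    te_ms: tuple[float, float, float, float] = DEFAULT_TE_MS,
) -> list[np.ndarray]:
    """Evaluate the piecewise SAGE signal equations at the four echoes."""
    r2 = 1000.0 / np.asarray(t2_ms, dtype=np.float64)
    r2s = 1000.0 / np.asarray(t2star_ms, dtype=np.float64)
    te = np.asarray(te_ms, dtype=np.float64) / 1000.0  # s
    te_se = te[3]
    out = []
    for i, tau in enumerate(te):
        if i < 2:
            out.append(s0_i * np.exp(-tau * r2s))
        else:
            out.append(s0_ii * np.exp(-te_se * (r2s - r2)) * np.exp(-tau * (2.0 * r2 - r2s)))
    return out


def solve_sage(echoes: SageEchoSet, refine: bool = False) -> tuple[ImageVolume, ImageVolume]:
    """Closed-form qT2 and qT2* maps (ms) from a 4-echo SAGE set.

    Voxels with a nonpositive signal, or whose within-regime signals do
    not decay (R2 or R2* ≤ 0), are invalid (NaN).  qT2 ≥ qT2* is *not*
    enforced: noise may invert the ordering and clamping would bias ROI
    medians.  With exactly four echoes the closed form interpolates the
    data (zero residual), so ``refine`` currently changes nothing and is
    accepted for interface compatibility with over-determined multi-echo
    variants.
    """
    s = [np.asarray(e.data, dtype=np.float64) for e in echoes.echoes]
    te = np.asarray(echoes.te_ms, dtype=np.float64) / 1000.0  # s
    positive = np.ones_like(s[0], dtype=bool)
    for arr in s:
        positive &= arr > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r2s = np.log(s[0] / s[1]) / (te[1] - te[0])
        spin_slope = np.log(s[2] / s[3]) / (te[3] - te[2])  # = 2·R2 − R2*
        r2 = 0.5 * (spin_slope + r2s)
        qt2star = 1000.0 / r2s
        qt2 = 1000.0 / r2
    valid = positive & (r2s > 0) & (r2 > 0)
    qt2 = np.where(valid, qt2, np.nan)
    qt2star = np.where(valid, qt2star, np.nan)
    n_invalid = int((~valid).sum())
    if n_invalid:
        log.info("solve_sage: %d voxels invalid (nonpositive or nonmonotone signals)", n_invalid)
    spacing = echoes.echoes[0].spacing
    frame = echoes.echoes[0].frame_id
    return (
        ImageVolume(data=qt2, spacing=spacing, frame_id=frame),
        ImageVolume(data=qt2star, spacing=spacing, frame_id=frame),
    )


def roi_qt2_medians(
    qt2: ImageVolume,
    qt2star: ImageVolume,
    mask: BinaryMask,
) -> tuple[float, float]:
    """Median qT2 and qT2* (ms) over valid tumor voxels.

    Returns NaNs when the ROI has no valid voxel, marking the lesion as
    missing for relaxometry.
    """
    v2 = masked_values(qt2, mask)
    v2s = masked_values(qt2star, mask)
    if v2.size == 0 and v2s.size == 0:
        log.warning("roi_qt2_medians: no valid relaxometry voxels in ROI")
        return float("nan"), float("nan")
    m2 = float(np.median(v2)) if v2.size else float("nan")
    m2s = float(np.median(v2s)) if v2s.size else float("nan")
    return m2, m2s
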