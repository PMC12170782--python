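"""Closed-form per-voxel maps: ADC from a two-b-value DWI pair and
deltaT1 from intensity-normalized pre/post-contrast T1-weighted images.

ADC follows the monoexponential model S(b) = S(0)·exp(−b·ADC); with the
standard clinical pair b = 0 and b = 1000 s/mm² this reduces to a single
log-ratio per voxel.  deltaT1 is the voxelwise difference of post- minus
pre-contrast T1-weighted images after each image is scaled so its median
within the brain equals one; it is a semiquantitative measure of
contrast enhancement (blood-brain-barrier permeability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import BinaryMask, ImageVolume, check_same_grid
from .errors import NormalizationError, ParameterError

log = logging.getLogger(__name__)

__all__ = ["DwiPair", "DeltaT1Inputs", "compute_adc", "compute_delta_t1"]


@dataclass
class DwiPair:
    """Two diffusion-weighted volumes with their b-values (s/mm²)."""

    s_b0: ImageVolume
    s_b1000: ImageVolume
    b_low: float = 0.0
    b_high: float = 1000.0

    def __post_init__(self) -> None:
        if not self.b_high > self.b_low >= 0:
            raise ParameterError(f"need b_high > b_low >= 0, got ({self.b_low}, {self.b_high})")
        check_same_grid(self.s_b0, self.s_b1000)


@dataclass
class DeltaT1Inputs:
    """Pre/post-contrast T1-weighted images plus the brain mask used
    for intensity normalization."""

    t1w_pre: ImageVolume
    t1w_post: ImageVolume
    brain: BinaryMask

    def __post_init__(self) -> None:
        check_same_grid(self.t1w_pre, self.t1w_post, self.brain)


def compute_adc(pair: DwiPair) -> ImageVolume:
    """Apparent diffusion coefficient map in µm²/s.

    ADC = ln(S_b0 / S_b1000) / (b_high − b_low), converted from mm²/s to
    µm²/s (×10⁶).  Voxels with a nonpositive signal or with
    S_b1000 > S_b0 (negative apparent diffusivity) are set NaN rather
    than clamped, so downstream medians stay honest.
    """
    s0 = pair.s_b0.data.astype(np.float64)
    s1 = pair.s_b1000.data.astype(np.float64)
    db = pair.b_high - pair.b_low  # s/mm²
    with np.errstate(divide="ignore", invalid="ignore"):
        adc = np.log(s0 / s1) / db * 1e6
    invalid = (s0 <= 0) | (s1 <= 0) | (adc < 0)
    adc = np.where(invalid, np.nan, adc)
    n_bad = int(invalid.sum())
    if n_bad:
        log.info("compute_adc: %d voxels invalid (nonpositive or inverted signal)", n_bad)
    return ImageVolume(data=adc, spacing=pair.s_b0.spacing, frame_id=pair.s_b0.frame_id)


def _normalize_by_brain_median(img: ImageVolume, brain: BinaryMask) -> np.ndarray:
    vals = img.data[brain.data]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise NormalizationError("empty brain mask")
    med = float(np.median(vals))
    if med <= 0:
        raise NormalizationError(f"nonpositive brain-median intensity ({med})")
    return img.data / med


def compute_delta_t1(inp: DeltaT1Inputs) -> ImageVolume:
    """T1-weighted subtraction map (deltaT1).

    Each image is divided by its median intensity within the brain mask,
    then deltaT1 = post − pre.  The normalization removes arbitrary
    scanner scaling, so a pure global rescale of either image leaves the
    map unchanged.
    """
    pre = _normalize_by_brain_median(inp.t1w_pre, inp.brain)
    post = _normalize_by_brain_median(inp.t1w_post, inp.brain)
    return ImageVolume(
        data=post - pre,
        spacing=inp.t1w_pre.spacing,
        frame_id=inp.t1w_pre.frame_id,
    )
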