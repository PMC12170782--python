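"""Volumetric data model and NIfTI I/O shared by all pipeline stages.

Every per-voxel map produced by the package (ADC, rCBV, MTR_asym, qT2,
qT2*, deltaT1) lives in an :class:`ImageVolume`; tumor and brain
segmentations live in a :class:`BinaryMask`.  All stages assume a single
common grid: volumes are combinable only when shape, voxel spacing and
frame identity agree, and no resampling is ever performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, GridMismatchError

log = logging.getLogger(__name__)

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "masked_values",
    "check_same_grid",
]


@dataclass
class ImageVolume:
    """A 3D scalar map on a fixed grid.

    Parameters
    ----------
    data:
        3D array of map values; units depend on the map (µm²/s for ADC,
        ms for qT2/qT2*, % for MTR_asym, dimensionless for rCBV/deltaT1).
        Non-finite voxels mark invalid measurements.
    spacing:
        Per-axis voxel size in mm; all entries must be positive.
    frame_id:
        Identifier of the common grid (e.g. the lesion id of the
        registration target).  ``None`` means unspecified and matches
        any frame.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    frame_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"expected 3D data, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"voxel spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class BinaryMask:
    """A 3D boolean segmentation on the common grid.

    ``kind`` distinguishes contrast-enhancing tumor masks (``tumor_ce``)
    from whole-brain masks (``brain``); tumor masks are expected to be
    subsets of the brain mask.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    kind: str = "tumor_ce"
    frame_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise FormatError(f"expected 3D mask, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"voxel spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def volume_cc(self) -> float:
        """Segmented volume in cm³ (voxel count × voxel volume / 1000)."""
        return self.n_voxels * self.voxel_volume_mm3 / 1000.0


def check_same_grid(*objs: ImageVolume | BinaryMask) -> None:
    """Raise :class:`GridMismatchError` unless all objects share one grid.

    Shape and spacing must match exactly; frame ids must agree where both
    are set (``None`` is a wildcard).
    """
    first = objs[0]
    for other in objs[1:]:
        if other.shape != first.shape:
            raise GridMismatchError(f"shape mismatch: {first.shape} vs {other.shape}")
        if not np.allclose(other.spacing, first.spacing, rtol=1e-6, atol=1e-6):
            raise GridMismatchError(f"spacing mismatch: {first.spacing} vs {other.spacing}")
        if first.frame_id is not None and other.frame_id is not None and first.frame_id != other.frame_id:
            raise GridMismatchError(f"frame mismatch: {first.frame_id!r} vs {other.frame_id!r}")


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"not a readable NIfTI image: {path}") from exc
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms)


def read_volume(path: str | Path, frame_id: str | None = None) -> ImageVolume:
    """Read a 3D scalar volume from a NIfTI file.

    4D containers with a single frame are squeezed to 3D.  Container
    scaling (scl_slope/scl_inter) is applied by nibabel.
    """
    data, spacing = _load_nifti(path)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D (or single-frame 4D) image, got shape {data.shape}")
    return ImageVolume(data=data.astype(np.float64), spacing=spacing, frame_id=frame_id)


def read_mask(path: str | Path, kind: str = "tumor_ce", frame_id: str | None = None) -> BinaryMask:
    """Read a binary mask (any nonzero voxel is True)."""
    data, spacing = _load_nifti(path)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D mask, got shape {data.shape}")
    return BinaryMask(data=data != 0, spacing=spacing, kind=kind, frame_id=frame_id)


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(vol: ImageVolume, path: str | Path) -> Path:
    """Write a volume as float32 NIfTI; lossless roundtrip for float32 data."""
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"no such directory: {path.parent}")
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"no such directory: {path.parent}")
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    return path


def masked_values(
    vol: ImageVolume,
    mask: BinaryMask,
    *,
    return_dropped: bool = False,
) -> np.ndarray | tuple[np.ndarray, int]:
    """Values of ``vol`` at the True voxels of ``mask``, non-finite dropped.

    Returns the 1D value array, plus the dropped-voxel count when
    ``return_dropped`` is set.  An all-false mask yields an empty array
    with a warning.
    """
    check_same_grid(vol, mask)
    raw = vol.data[mask.data]
    finite = np.isfinite(raw)
    dropped = int(raw.size - finite.sum())
    if raw.size == 0:
        log.warning("masked_values: empty mask")
    if dropped:
        log.info("masked_values: dropped %d non-finite of %d voxels", dropped, raw.size)
    values = raw[finite]
    if return_dropped:
        return values, dropped
    return values
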