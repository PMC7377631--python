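"""Core in-memory containers shared across the pipeline.

The pipeline moves data through three containers: a :class:`CTVolume` of
Hounsfield-unit intensities, a :class:`BoneMask` of thresholded skull voxels,
and a :class:`ProjectedImage` — the square binary suture map (bone = 1,
suture/gap = 0) that the classifier consumes.

All three use (x, y, z) index order with z pointing superior (toward the
vertex); axial slices are stacked inferior -> superior, so ``voxels[:, :, 0]``
is the bottom slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["CTVolume", "BoneMask", "ProjectedImage", "SphericalCoord"]


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be three positive floats, got {spacing!r}")
    return spacing


@dataclass(frozen=True)
class CTVolume:
    """A CT scan: a 3D grid of HU intensities with physical voxel spacing.

    Parameters
    ----------
    intensities
        3D array of Hounsfield units (air ~ -1000, soft tissue < 60,
        bone ~ +1000); any real dtype within the signed 16-bit range.
    spacing
        (dx, dy, dz) voxel edge lengths in millimetres, each > 0.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3 or any(d < 1 for d in arr.shape):
            raise ValidationError(f"intensities must be 3D with all dims >= 1, got shape {arr.shape}")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass(frozen=True)
class BoneMask:
    """Boolean grid of skull voxels, carrying the source volume's spacing."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValidationError(f"voxels must be 3D, got shape {arr.shape}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.isin(uniq, (0, 1)).all():
                raise ValidationError("mask voxels must be strictly binary")
            arr = arr.astype(bool)
        object.__setattr__(self, "voxels", arr)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def count(self) -> int:
        """Number of bone voxels."""
        return int(self.voxels.sum())


@dataclass(frozen=True)
class ProjectedImage:
    """N x N binary suture map: bone = 1, suture/gap/background = 0."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValidationError(f"projected image must be square 2D, got shape {arr.shape}")
        if arr.dtype != np.uint8 or not np.isin(np.unique(arr), (0, 1)).all():
            uniq = np.unique(arr)
            if not np.isin(uniq, (0, 1)).all():
                raise ValidationError("projected image pixels must be 0/1")
            arr = arr.astype(np.uint8)
        object.__setattr__(self, "pixels", arr)

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class SphericalCoord:
    """Spherical polar coordinates of a voxel relative to the projection origin.

    ``r`` is the radial distance in mm; ``theta`` the *signed* polar angle and
    ``phi`` the azimuth, both folded into [-pi/2, pi/2] so the pair covers the
    hemisphere above the origin plane (see :mod:`suturemap.projection`).
    """

    r: float
    theta: float
    phi: float

    def __post_init__(self) -> None:
        half = np.pi / 2 + 1e-12
        if self.r < 0:
            raise ValidationError("r must be >= 0")
        if not (-half <= self.theta <= half and -half <= self.phi <= half):
            raise ValidationError("theta and phi must lie in [-pi/2, pi/2]")
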