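"""Bone segmentation of CT volumes by Hounsfield-unit thresholding.

Cortical bone in an infant skull sits near +1000 HU while brain and scalp stay
below ~60 HU, so a single global threshold separates skull from soft tissue.
The default cutoff is 300 HU with a *strict* inequality: a voxel belongs to
the skull iff its intensity is greater than the threshold.  No morphological
cleanup is applied by default; an optional largest-connected-component filter
can drop disconnected bone fragments (e.g. vertebrae) before projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datatypes import BoneMask, CTVolume
from .errors import EmptySkullError

__all__ = ["SegmentationConfig", "segment_bone", "crop_to_skull", "largest_component"]

#: HU cutoff separating bone from soft tissue.
DEFAULT_THRESHOLD_HU = 300.0


@dataclass(frozen=True)
class SegmentationConfig:
    """Segmentation parameters.

    Parameters
    ----------
    threshold_hu
        Voxels strictly above this HU value are bone.  Default 300.
    keep_largest_component
        If True, keep only the largest 26-connected bone component.
        Off by default: raw thresholding is the reference behaviour.
    """

    threshold_hu: float = DEFAULT_THRESHOLD_HU
    keep_largest_component: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold_hu):
            raise ValueError("threshold_hu must be finite")


def segment_bone(vol: CTVolume, cfg: SegmentationConfig | None = None) -> BoneMask:
    """Threshold a CT volume into a binary skull mask.

    A voxel is bone iff ``intensity > cfg.threshold_hu`` (strict, so a voxel
    of exactly 300 HU is excluded at the default).  An empty result is legal.
    """
    cfg = cfg or SegmentationConfig()
    voxels = np.asarray(vol.intensities) > cfg.threshold_hu
    if cfg.keep_largest_component and voxels.any():
        voxels = largest_component(voxels)
    return BoneMask(voxels=voxels, spacing=vol.spacing)


def largest_component(voxels: np.ndarray) -> np.ndarray:
    """Keep only the largest 26-connected True component."""
    labels, n = ndimage.label(voxels, structure=np.ones((3, 3, 3), dtype=int))
    if n <= 1:
        return voxels.copy()
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background
    return labels == int(counts.argmax())


def crop_to_skull(mask: BoneMask) -> tuple[BoneMask, tuple[int, int, int]]:
    """Crop a mask to the tight bounding box of its bone voxels.

    Returns the cropped mask and the integer index offset of the crop's
    corner in the original grid, so original indices are recovered as
    ``cropped_index + offset``.

    Raises
    ------
    EmptySkullError
        If the mask has no bone voxels.
    """
    if not mask.voxels.any():
        raise EmptySkullError("cannot crop an empty bone mask")
    lo, hi = [], []
    for axis in range(3):
        profile = mask.voxels.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(profile)
        lo.append(int(idx[0]))
        hi.append(int(idx[-1]))
    cropped = mask.voxels[lo[0]: hi[0] + 1, lo[1]: hi[1] + 1, lo[2]: hi[2] + 1]
    return BoneMask(voxels=cropped, spacing=mask.spacing), (lo[0], lo[1], lo[2])
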