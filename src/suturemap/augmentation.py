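"""Constrained augmentation of binary suture maps.

Each projected case is expanded into a fixed set of flipped, rotated and
rescaled variants.  Magnitudes are deliberately small (rotations within
±15 degrees, scale within [0.85, 1.15]): a large transform can slide the
open-suture pattern of one subtype toward another's (an anterior gap pushed
posteriorly), teaching the classifier a biased distribution.  All resampling
is nearest-neighbour so the images stay strictly binary, and the whole
recipe is deterministic — no hidden randomness.

The default recipe has exactly 61 entries: 3 pure flips, 10 pure rotations
(±3, ±6, ±9, ±12, ±15 deg), 6 pure rescales (0.85–1.15 in steps of 0.05,
skipping 1.0), all 30 flip x rotation pairs, and the 12 horizontal/vertical
flip x rescale pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import ndimage

from .datatypes import ProjectedImage
from .errors import ValidationError

__all__ = [
    "TransformSpec",
    "AugmentationRecipe",
    "default_recipe",
    "apply_transform",
    "augment_case",
]

FLIPS = ("none", "horizontal", "vertical", "both")
ROTATION_LIMIT_DEG = 15.0
SCALE_RANGE = (0.85, 1.15)

_ROTATIONS = (-15.0, -12.0, -9.0, -6.0, -3.0, 3.0, 6.0, 9.0, 12.0, 15.0)
_SCALES = (0.85, 0.90, 0.95, 1.05, 1.10, 1.15)


@dataclass(frozen=True)
class TransformSpec:
    """One augmentation step: an optional flip, rotation and rescale.

    ``rotation_deg`` is counter-clockwise about the image centre, capped at
    ±15; ``scale`` is an isotropic factor in [0.85, 1.15] (down-scaling pads
    the border with 0, up-scaling centre-crops).
    """

    flip: str = "none"
    rotation_deg: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.flip not in FLIPS:
            raise ValidationError(f"flip must be one of {FLIPS}, not {self.flip!r}")
        if abs(self.rotation_deg) > ROTATION_LIMIT_DEG:
            raise ValidationError(f"|rotation| must be <= {ROTATION_LIMIT_DEG} deg")
        if not (SCALE_RANGE[0] <= self.scale <= SCALE_RANGE[1]):
            raise ValidationError(f"scale must lie in {SCALE_RANGE}")

    @property
    def is_identity(self) -> bool:
        return self.flip == "none" and self.rotation_deg == 0.0 and self.scale == 1.0


@dataclass(frozen=True)
class AugmentationRecipe:
    """An ordered, identity-free list of transforms applied to every case."""

    transforms: tuple[TransformSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "transforms", tuple(self.transforms))
        if any(t.is_identity for t in self.transforms):
            raise ValidationError("a recipe must not contain the identity transform")

    def __len__(self) -> int:
        return len(self.transforms)

    def __iter__(self):
        return iter(self.transforms)


def default_recipe() -> AugmentationRecipe:
    """The fixed 61-transform recipe applied to each case."""
    specs: list[TransformSpec] = []
    specs += [TransformSpec(flip=f) for f in ("horizontal", "vertical", "both")]
    specs += [TransformSpec(rotation_deg=r) for r in _ROTATIONS]
    specs += [TransformSpec(scale=s) for s in _SCALES]
    specs += [
        TransformSpec(flip=f, rotation_deg=r)
        for f in ("horizontal", "vertical", "both")
        for r in _ROTATIONS
    ]
    specs += [
        TransformSpec(flip=f, scale=s)
        for f in ("horizontal", "vertical")
        for s in _SCALES
    ]
    assert len(specs) == 61
    return AugmentationRecipe(transforms=tuple(specs))


def apply_transform(img: ProjectedImage, t: TransformSpec) -> ProjectedImage:
    """Apply flip, then rotation, then rescale; output is binary and same size."""
    a = img.pixels
    if t.flip in ("horizontal", "both"):
        a = a[:, ::-1]
    if t.flip in ("vertical", "both"):
        a = a[::-1, :]
    if t.rotation_deg != 0.0:
        a = ndimage.rotate(
            a, t.rotation_deg, reshape=False, order=0,
            mode="constant", cval=0, prefilter=False,
        )
    if t.scale != 1.0:
        a = _rescale(a, t.scale)
    return ProjectedImage(pixels=np.ascontiguousarray(a, dtype=np.uint8))


def _rescale(a: np.ndarray, scale: float) -> np.ndarray:
    """Nearest-neighbour rescale about the centre, keeping the frame size."""
    n = a.shape[0]
    s = int(np.floor(scale * n))
    if s == n:
        return a
    src = (np.arange(s) / scale).astype(np.int64)
    np.clip(src, 0, n - 1, out=src)
    resized = a[np.ix_(src, src)]
    if s < n:  # shrink: zero-pad the border
        out = np.zeros((n, n), dtype=a.dtype)
        off = (n - s) // 2
        out[off: off + s, off: off + s] = resized
        return out
    off = (s - n) // 2  # grow: centre-crop
    return resized[off: off + n, off: off + n]


def augment_case(
    img: ProjectedImage, recipe: AugmentationRecipe | Iterable[TransformSpec]
) -> list[ProjectedImage]:
    """One augmented image per recipe entry, in recipe order; deterministic."""
    return [apply_transform(img, t) for t in recipe]
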