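"""Parametric CT phantoms of infant skulls with subtype-specific suture fusion.

The phantom is a stylised cranial vault: an ellipsoidal bone shell
(~1000 HU) enclosing soft tissue (~40 HU) in air (-1000 HU), carrying three
great-circle suture bands — a midline sagittal band split into anterior,
middle and posterior thirds, plus coronal and lambdoid bands.  Each band
segment has a *fused fraction* in [0, 1]: the unfused part is carved out of
the shell (set to soft tissue) so it projects as an open gap, the fused part
stays bone.  The four sagittal-craniosynostosis subtypes are encoded as
fusion patterns:

- ``anterior``   — anterior sagittal third fused, mild antero-posterior
  elongation of the vault (frontal bossing / scaphocephaly).
- ``central``    — middle sagittal third fused with a locally thickened
  ("heaped-up") ridge along the fused band.
- ``posterior``  — posterior sagittal third fused, occipital elongation.
- ``complex``    — two or more regions fused (anterior + posterior sagittal
  plus partially fused coronal/lambdoid).

The layout is deliberately not anatomically exact; it provides projectable
gap geometry whose class signal lives in *which* part of the sagittal band
is closed, which is what the downstream classifier must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import CTVolume
from .errors import ResolutionError, ValidationError

__all__ = [
    "SUBTYPES",
    "SUTURE_SEGMENTS",
    "PhantomSpec",
    "subtype_spec",
    "generate_phantom",
    "cohort_specs",
    "phantom_cohort",
]

SUBTYPES = ("anterior", "central", "posterior", "complex")

SUTURE_SEGMENTS = (
    "sagittal_anterior",
    "sagittal_middle",
    "sagittal_posterior",
    "coronal",
    "lambdoid",
)

#: Open-suture baseline for a healthy infant vault (everything mostly open).
_OPEN = {s: 0.1 for s in SUTURE_SEGMENTS}

_SUBTYPE_FUSION: dict[str, dict[str, float]] = {
    "anterior": {**_OPEN, "sagittal_anterior": 0.95, "coronal": 0.3, "lambdoid": 0.3},
    "central": {**_OPEN, "sagittal_middle": 0.95, "coronal": 0.3, "lambdoid": 0.3},
    "posterior": {**_OPEN, "sagittal_posterior": 0.95, "coronal": 0.3, "lambdoid": 0.3},
    "complex": {
        **_OPEN,
        "sagittal_anterior": 0.9,
        "sagittal_posterior": 0.9,
        "sagittal_middle": 0.3,
        "coronal": 0.6,
        "lambdoid": 0.6,
    },
}


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of one synthetic skull.

    Axes: x lateral, y antero-posterior (+y anterior), z inferior->superior.
    The vault ellipsoid has semi-axes ``radii_mm``; like a clinical head CT
    the series is truncated at the skull base, so the grid's bottom slice
    cuts the ellipsoid ``base_cut_frac * rz`` above its lowest point and the
    bottom slice is a wide ring of bone rather than a closed tip.
    """

    subtype: str = "anterior"
    radii_mm: tuple[float, float, float] = (42.0, 55.0, 45.0)
    shell_thickness_mm: float = 3.0
    suture_width_mm: float = 3.0
    fusion: dict[str, float] = field(default_factory=lambda: dict(_OPEN))
    ridged: bool = False
    ridge_factor: float = 1.6
    bone_hu: float = 1000.0
    soft_hu: float = 40.0
    air_hu: float = -1000.0
    noise_sd_hu: float = 20.0
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shape: tuple[int, int, int] = (128, 128, 128)
    base_cut_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValidationError(f"subtype must be one of {SUBTYPES}")
        if min(self.radii_mm) <= 0 or self.shell_thickness_mm <= 0 or self.suture_width_mm <= 0:
            raise ValidationError("radii, shell thickness and suture width must be positive")
        if set(self.fusion) - set(SUTURE_SEGMENTS):
            raise ValidationError(f"unknown suture segments: {set(self.fusion) - set(SUTURE_SEGMENTS)}")
        if any(not 0.0 <= f <= 1.0 for f in self.fusion.values()):
            raise ValidationError("fusion fractions must lie in [0, 1]")
        if self.noise_sd_hu < 0:
            raise ValidationError("noise_sd_hu must be >= 0")


def subtype_spec(subtype: str, seed: int = 0, **overrides) -> PhantomSpec:
    """Preset spec for one subtype: fusion pattern, shape change, ridging."""
    if subtype not in SUBTYPES:
        raise ValidationError(f"subtype must be one of {SUBTYPES}")
    base = PhantomSpec(seed=seed)
    radii = list(base.radii_mm)
    if subtype in ("anterior", "posterior"):
        radii[1] *= 1.08  # antero-posterior elongation
    spec = replace(
        base,
        subtype=subtype,
        radii_mm=tuple(radii),
        fusion=dict(_SUBTYPE_FUSION[subtype]),
        ridged=(subtype == "central"),
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def _segment_open_mask(
    spec: PhantomSpec, X: np.ndarray, Y: np.ndarray, Z: np.ndarray,
    cx: float, cy: float, cz: float,
) -> np.ndarray:
    """Boolean mask of *open* (to-be-carved) suture voxels, upper vault only."""
    rx, ry, rz = spec.radii_mm
    w = spec.suture_width_mm / 2.0
    upper = Z > cz
    third = ry / 3.0
    open_mask = np.zeros(X.shape, dtype=bool)

    sag = upper & (np.abs(X - cx) <= w)
    f = spec.fusion
    # Anterior third fuses from the frontal tip backwards.
    u_ant = (Y - (cy + third)) / (ry - third)
    open_mask |= sag & (Y - cy > third) & (u_ant < 1.0 - f.get("sagittal_anterior", 0.0))
    # Posterior third fuses from the occipital tip forwards.
    u_pos = ((cy - third) - Y) / (ry - third)
    open_mask |= sag & (Y - cy < -third) & (u_pos < 1.0 - f.get("sagittal_posterior", 0.0))
    # Middle third fuses outward from the vertex.
    u_mid = np.abs(Y - cy) / third
    open_mask |= sag & (np.abs(Y - cy) <= third) & (u_mid > f.get("sagittal_middle", 0.0))
    # Coronal / lambdoid bands fuse outward from the midline.
    u_lat = np.abs(X - cx) / rx
    for name, y_off in (("coronal", 0.55 * ry), ("lambdoid", -0.55 * ry)):
        band = upper & (np.abs(Y - (cy + y_off)) <= w)
        open_mask |= band & (u_lat > f.get(name, 0.0))
    return open_mask


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, str]:
    """Render one phantom CT volume; fully deterministic given ``spec.seed``.

    Raises
    ------
    ResolutionError
        If the bone shell is thinner than one voxel and would vanish.
    """
    dx, dy, dz = spec.spacing_mm
    if spec.shell_thickness_mm < max(spec.spacing_mm):
        raise ResolutionError(
            f"shell thickness {spec.shell_thickness_mm} mm is below the voxel "
            f"size {max(spec.spacing_mm)} mm; the shell would not be closed"
        )
    nx, ny, nz = spec.shape
    rx, ry, rz = spec.radii_mm
    cx, cy = (nx - 1) / 2.0 * dx, (ny - 1) / 2.0 * dy
    cz = (1.0 - spec.base_cut_frac) * rz  # ellipsoid truncated by the grid bottom
    X, Y, Z = np.meshgrid(
        np.arange(nx) * dx, np.arange(ny) * dy, np.arange(nz) * dz, indexing="ij"
    )

    def ellipsoid(radii: tuple[float, float, float]) -> np.ndarray:
        return (
            ((X - cx) / radii[0]) ** 2
            + ((Y - cy) / radii[1]) ** 2
            + ((Z - cz) / radii[2]) ** 2
        ) <= 1.0

    t = spec.shell_thickness_mm
    outer = ellipsoid((rx, ry, rz))
    inner = ellipsoid((rx - t, ry - t, rz - t))
    bone = outer & ~inner

    if spec.ridged:
        # Heaped-up ridge: locally thicker shell along the middle sagittal band.
        t2 = spec.ridge_factor * t
        inner2 = ellipsoid((rx - t2, ry - t2, rz - t2))
        ridge_zone = (
            (np.abs(X - cx) <= 1.5 * spec.suture_width_mm)
            & (np.abs(Y - cy) <= ry / 3.0)
            & (Z > cz)
        )
        bone |= outer & ~inner2 & ridge_zone

    bone &= ~_segment_open_mask(spec, X, Y, Z, cx, cy, cz)

    hu = np.full(spec.shape, spec.air_hu, dtype=np.float64)
    hu[outer] = spec.soft_hu  # interior + carved suture voxels
    hu[bone] = spec.bone_hu
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        hu += rng.normal(0.0, spec.noise_sd_hu, size=hu.shape)
    hu = np.clip(np.rint(hu), -32768, 32767).astype(np.int16)
    return CTVolume(intensities=hu, spacing=spec.spacing_mm), spec.subtype


def cohort_specs(
    n_per_class: int,
    seed: int = 0,
    radii_jitter: float = 0.08,
    fusion_jitter: float = 0.08,
    **overrides,
) -> list[PhantomSpec]:
    """Class-balanced list of 4 * n_per_class jittered phantom specs.

    Radii are scaled by independent uniform factors in [1 - radii_jitter,
    1 + radii_jitter]; fusion fractions are shifted by uniform noise within
    ±fusion_jitter and clipped to [0, 1].  Reproducible from ``seed``;
    ``overrides`` are forwarded to every spec (e.g. ``noise_sd_hu=0``).
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    specs: list[PhantomSpec] = []
    for subtype in SUBTYPES:
        for _ in range(n_per_class):
            base = subtype_spec(subtype, **overrides)
            radii = tuple(
                r * rng.uniform(1 - radii_jitter, 1 + radii_jitter) if radii_jitter else r
                for r in base.radii_mm
            )
            fusion = {
                k: float(np.clip(v + (rng.uniform(-fusion_jitter, fusion_jitter) if fusion_jitter else 0.0), 0, 1))
                for k, v in base.fusion.items()
            }
            specs.append(
                replace(base, radii_mm=radii, fusion=fusion,
                        seed=int(rng.integers(0, 2**31 - 1)))
            )
    return specs


def phantom_cohort(
    n_per_class: int,
    seed: int = 0,
    radii_jitter: float = 0.08,
    fusion_jitter: float = 0.08,
    **overrides,
) -> list[tuple[CTVolume, str]]:
    """Generate a labeled, class-balanced phantom cohort (see :func:`cohort_specs`)."""
    return [generate_phantom(s) for s in cohort_specs(
        n_per_class, seed=seed, radii_jitter=radii_jitter,
        fusion_jitter=fusion_jitter, **overrides,
    )]
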