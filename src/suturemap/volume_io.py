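"""Reading CT volumes and reading/writing binary suture maps.

Volumes are accepted as NIfTI (``.nii``/``.nii.gz``) or NRRD files and are
normalised to a common convention on load: intensities in Hounsfield units,
(x, y, z) index order, axial slices ordered by ascending physical z (inferior
to superior), spacing taken from the header.  A DICOM series directory is part
of the documented interface but needs a DICOM parser that is not available in
this distribution, so it raises :class:`UnsupportedFormatError` with an
explanatory message.

Projected suture maps go to disk as 8-bit grayscale PNG with the rendering
convention bone = 1 -> black (0) and suture/gap = 0 -> white (255), so open
sutures appear as white tracks on a black skull.
"""

from __future__ import annotations

import gzip
import os
import zlib
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .datatypes import CTVolume, ProjectedImage
from .errors import UnsupportedFormatError, ValidationError

__all__ = [
    "read_ct_volume",
    "write_ct_volume",
    "read_binary_image",
    "write_binary_image",
]


def read_ct_volume(path: str | os.PathLike) -> CTVolume:
    """Read a CT volume from NIfTI or NRRD into HU with z = superior.

    Parameters
    ----------
    path
        A ``.nii``/``.nii.gz`` or ``.nrrd`` file.  A directory (DICOM series)
        is recognised but unsupported in this build.

    Returns
    -------
    CTVolume
        Intensities in HU (header scale/slope applied by the reader),
        spacing in mm from the header.
    """
    path = Path(path)
    if path.is_dir():
        raise UnsupportedFormatError(
            "DICOM series directories need pydicom, which is not bundled; "
            "convert the series to NIfTI (e.g. dcm2niix) and retry"
        )
    if not path.exists():
        raise UnsupportedFormatError(f"no such file: {path}")
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return _read_nifti(path)
    if name.endswith(".nrrd"):
        return _read_nrrd(path)
    raise UnsupportedFormatError(f"unrecognised volume format: {path.name}")


def _read_nifti(path: Path) -> CTVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise UnsupportedFormatError(f"could not read NIfTI file {path}: {exc}") from exc
    # Reorient to RAS so the third axis ascends toward the superior direction.
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.get_fdata())  # applies scl_slope / scl_inter
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(intensities=data, spacing=spacing)


_NRRD_DTYPES = {
    "signed char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "signed short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "signed int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "double": "f8",
}


def _read_nrrd(path: Path) -> CTVolume:
    """Minimal NRRD reader: raw/gzip encodings, 3D, diagonal space directions."""
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise UnsupportedFormatError(f"{path} is not an NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii", "replace").strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, _, value = text.partition(":")
            fields[key.strip().lower()] = value.lstrip("=").strip()
        payload = fh.read()

    if int(fields.get("dimension", "0")) != 3:
        raise UnsupportedFormatError("only 3D NRRD volumes are supported")
    sizes = tuple(int(s) for s in fields["sizes"].split())
    dtype = _NRRD_DTYPES.get(fields.get("type", "").lower())
    if dtype is None:
        raise UnsupportedFormatError(f"unsupported NRRD type {fields.get('type')!r}")
    endian = "<" if fields.get("endian", "little").lower() == "little" else ">"
    encoding = fields.get("encoding", "raw").lower()
    if encoding in ("gzip", "gz"):
        try:
            payload = gzip.decompress(payload)
        except (OSError, zlib.error) as exc:
            raise UnsupportedFormatError(f"corrupt gzip payload in {path}") from exc
    elif encoding != "raw":
        raise UnsupportedFormatError(f"unsupported NRRD encoding {encoding!r}")

    expected = int(np.prod(sizes)) * np.dtype(dtype).itemsize
    if len(payload) < expected:
        raise UnsupportedFormatError(f"truncated NRRD payload in {path}")
    flat = np.frombuffer(payload[:expected], dtype=endian + dtype)
    # NRRD stores the first listed axis fastest; numpy reshape is slowest-first.
    data = flat.reshape(sizes[::-1]).transpose(2, 1, 0)

    spacing = _nrrd_spacing(fields)
    return CTVolume(intensities=np.ascontiguousarray(data), spacing=spacing)


def _nrrd_spacing(fields: dict[str, str]) -> tuple[float, float, float]:
    if "spacings" in fields:
        return tuple(float(s) for s in fields["spacings"].split())
    if "space directions" in fields:
        spacing = []
        for token in fields["space directions"].replace(") ", ")|").split("|"):
            vec = [float(v) for v in token.strip("() ").split(",")]
            spacing.append(float(np.linalg.norm(vec)))
        return tuple(spacing)
    return (1.0, 1.0, 1.0)


def write_ct_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI with a diagonal affine built from its spacing."""
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(vol.intensities), affine), str(path))


def write_binary_image(img: ProjectedImage, path: str | os.PathLike) -> None:
    """Write a suture map as 8-bit grayscale PNG (bone -> black, gap -> white)."""
    rendered = ((1 - img.pixels) * 255).astype(np.uint8)
    Image.fromarray(rendered, mode="L").save(str(path), format="PNG")


def read_binary_image(path: str | os.PathLike) -> ProjectedImage:
    """Read a PNG suture map written by :func:`write_binary_image`.

    Raises
    ------
    ValidationError
        If the file holds pixel values other than pure black and white.
    """
    with Image.open(str(path)) as im:
        arr = np.asarray(im.convert("L"))
    values = np.unique(arr)
    if not np.isin(values, (0, 255)).all():
        raise ValidationError(
            f"{path} is not a binary suture map (pixel values {values[:8].tolist()}...)"
        )
    return ProjectedImage(pixels=(arr == 0).astype(np.uint8))
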