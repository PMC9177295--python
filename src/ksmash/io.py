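"""File formats: raw complex grids with JSON sidecars, PNG and NIfTI export.

Complex K-space and image grids are stored as raw little-endian float32
(real, imaginary) pairs in row-major order — coils stacked, slowest first —
next to a ``.json`` sidecar carrying shape, field of view, sampling mask
and coil count.  Magnitude images can additionally be written as 8-bit PNG
(display) or NIfTI (interchange with medical-imaging tools).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .kspace import ImagePlane, KSpaceGrid, MultiCoilKSpace, ValidationError

__all__ = [
    "write_kspace",
    "read_kspace",
    "write_image",
    "read_image",
    "write_png",
    "write_nifti",
]

_RAW_SUFFIX = ".raw"
_META_SUFFIX = ".json"


def _base(path) -> Path:
    p = Path(path)
    if p.suffix in (_RAW_SUFFIX, _META_SUFFIX):
        p = p.with_suffix("")
    return p


def _write_raw(base: Path, arr: np.ndarray, meta: dict) -> None:
    base.parent.mkdir(parents=True, exist_ok=True)
    interleaved = np.empty(arr.shape + (2,), dtype="<f4")
    interleaved[..., 0] = arr.real
    interleaved[..., 1] = arr.imag
    interleaved.tofile(base.with_suffix(_RAW_SUFFIX))
    base.with_suffix(_META_SUFFIX).write_text(json.dumps(meta, indent=2))


def _read_raw(base: Path) -> tuple[np.ndarray, dict]:
    meta = json.loads(base.with_suffix(_META_SUFFIX).read_text())
    flat = np.fromfile(base.with_suffix(_RAW_SUFFIX), dtype="<f4")
    shape = tuple(meta["shape"])
    data = flat.reshape(shape + (2,))
    return data[..., 0] + 1j * data[..., 1], meta


def write_kspace(data: KSpaceGrid | MultiCoilKSpace, path) -> Path:
    """Write a (multi-coil) K-space grid as raw complex + JSON sidecar."""
    base = _base(path)
    if isinstance(data, KSpaceGrid):
        data = MultiCoilKSpace([data])
    stack = data.stack()
    meta = {
        "kind": "kspace",
        "shape": list(stack.shape),
        "n_coils": data.n_coils,
        "dk_x": data.dk_x,
        "dk_y": data.dk_y,
        "mask": [bool(v) for v in data.mask],
    }
    _write_raw(base, stack, meta)
    return base.with_suffix(_META_SUFFIX)


def read_kspace(path) -> MultiCoilKSpace:
    base = _base(path)
    arr, meta = _read_raw(base)
    if meta.get("kind") != "kspace":
        raise ValidationError(f"{base}: not a K-space file")
    mask = np.asarray(meta["mask"], dtype=bool)
    # float32 round-trip can leave tiny nonzeros only on sampled rows;
    # masked rows were written as exact zeros.
    grids = [
        KSpaceGrid(samples=c, dk_x=meta["dk_x"], dk_y=meta["dk_y"], mask=mask)
        for c in arr
    ]
    return MultiCoilKSpace(grids)


def write_image(image: ImagePlane, path) -> Path:
    """Write a complex image as raw complex + JSON sidecar."""
    base = _base(path)
    meta = {
        "kind": "image",
        "shape": list(image.shape),
        "fov_x": image.fov_x,
        "fov_y": image.fov_y,
    }
    _write_raw(base, image.pixels, meta)
    return base.with_suffix(_META_SUFFIX)


def read_image(path) -> ImagePlane:
    base = _base(path)
    arr, meta = _read_raw(base)
    if meta.get("kind") != "image":
        raise ValidationError(f"{base}: not an image file")
    return ImagePlane(pixels=arr, fov_x=meta["fov_x"], fov_y=meta["fov_y"])


def write_png(image, path) -> Path:
    """Write a magnitude image as an 8-bit grayscale PNG (max-normalized)."""
    mag = image.magnitude if isinstance(image, ImagePlane) else np.abs(image)
    peak = mag.max()
    scaled = np.zeros_like(mag) if peak == 0 else mag / peak
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (scaled * 255).round().astype(np.uint8))
    return path


def write_nifti(image, path) -> Path:
    """Write a magnitude image as NIfTI with voxel size from the FOV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(image, ImagePlane):
        mag = image.magnitude
        zoom_x = 10.0 * image.fov_x / image.n_x  # cm -> mm voxels
        zoom_y = 10.0 * image.fov_y / image.n_y
    else:
        mag = np.abs(np.asarray(image))
        zoom_x = zoom_y = 1.0
    affine = np.diag([zoom_x, zoom_y, 1.0, 1.0])
    nib.save(nib.Nifti1Image(mag.T.astype(np.float32), affine), str(path))
    return path
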