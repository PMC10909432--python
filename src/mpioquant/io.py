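"""File formats: NIfTI volumes/masks, image renders with pixel-size sidecars.

Conventions: voxel indices are 0-based; volumes and masks must share their
grid exactly — no resampling is ever attempted, a mismatch is an error.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import tifffile

__all__ = [
    "read_volume",
    "write_volume",
    "check_same_grid",
    "write_image",
    "read_image",
]


def write_volume(
    path: str | Path,
    data: np.ndarray,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> Path:
    """Write a 3D volume (or boolean mask, stored uint8) as NIfTI-1."""
    path = Path(path)
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, ...], np.ndarray]:
    """Read a NIfTI volume; returns (data, voxel sizes in mm, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return data, tuple(float(z) for z in img.header.get_zooms()[:3]), img.affine


def check_same_grid(reference: np.ndarray, *others: np.ndarray, names: list[str] | None = None) -> None:
    """Raise with an explicit message when any array has a different shape."""
    names = names or [f"array {i}" for i in range(1 + len(others))]
    ref_shape = np.asarray(reference).shape
    for name, arr in zip(names[1:], others):
        if np.asarray(arr).shape != ref_shape:
            raise ValueError(
                f"grid mismatch: {name} has shape {np.asarray(arr).shape}, "
                f"expected {ref_shape} ({names[0]})"
            )


def write_image(path: str | Path, image: np.ndarray, pixel_size_um: float) -> Path:
    """Write an RGB render as TIFF or PNG with a JSON pixel-size sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), image)
    else:
        iio.imwrite(str(path), image)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"pixel_size_um": pixel_size_um}))
    return path


def read_image(path: str | Path) -> tuple[np.ndarray, float | None]:
    """Read an image and its pixel size (μm/px) from the JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        image = tifffile.imread(str(path))
    else:
        image = iio.imread(str(path))
    sidecar = path.with_suffix(path.suffix + ".json")
    pixel_size = None
    if sidecar.exists():
        pixel_size = json.loads(sidecar.read_text()).get("pixel_size_um")
    return np.asarray(image), pixel_size
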