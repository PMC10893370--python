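"""Reading and writing slices, masks, contours and manifests.

Slices: 8/16-bit PNG, TIFF, or single-slice NIfTI (pixel spacing taken from
the header, with an explicit argument as fallback).  Masks: PNG/NIfTI with
nonzero = inside.  Contours and run manifests are JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import tifffile

from .imaging import ImageSlice

__all__ = [
    "read_slice",
    "read_mask",
    "write_slice",
    "write_mask",
    "write_contours",
    "write_manifest",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_slice(path: str | Path, spacing: float | None = None) -> ImageSlice:
    """Read a 2-D grayscale slice; NIfTI spacing from the header."""
    path = Path(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).squeeze()
        if data.ndim != 2:
            raise ValueError(f"{path} is not a single 2-D slice")
        zooms = img.header.get_zooms()[:2]
        hdr_spacing = float(zooms[0])
        if abs(zooms[0] - zooms[1]) > 1e-6:
            if spacing is None:
                raise ValueError("anisotropic NIfTI spacing; pass spacing explicitly")
            hdr_spacing = spacing
        return ImageSlice(np.asarray(data, dtype=float), spacing or hdr_spacing)
    data = np.asarray(iio.imread(path), dtype=float)
    if data.ndim == 3:  # collapse RGB(A) to luminance
        data = data[..., :3].mean(axis=-1)
    return ImageSlice(data, spacing or 1.0)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask (nonzero = inside)."""
    path = Path(path)
    if _is_nifti(path):
        data = np.asanyarray(nib.load(str(path)).dataobj).squeeze()
    else:
        data = np.asarray(iio.imread(path))
        if data.ndim == 3:
            data = data[..., :3].max(axis=-1)
    return np.asarray(data) != 0


def write_slice(path: str | Path, slc: ImageSlice) -> None:
    """Write a slice as 16-bit TIFF or NIfTI (by extension)."""
    path = Path(path)
    if _is_nifti(path):
        affine = np.diag([slc.spacing, slc.spacing, 1.0, 1.0])
        nib.save(nib.Nifti1Image(slc.pixels.astype(np.float32), affine), str(path))
        return
    px = slc.pixels
    lo, hi = px.min(), px.max()
    scaled = np.zeros_like(px) if hi == lo else (px - lo) / (hi - lo)
    tifffile.imwrite(str(path), (scaled * 65535).astype(np.uint16))


def write_mask(path: str | Path, mask: np.ndarray, spacing: float = 1.0) -> None:
    """Write a binary mask as 8-bit PNG or NIfTI (by extension)."""
    path = Path(path)
    mask = np.asarray(mask, dtype=bool)
    if _is_nifti(path):
        affine = np.diag([spacing, spacing, 1.0, 1.0])
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))
        return
    iio.imwrite(path, (mask * 255).astype(np.uint8))


def write_contours(path: str | Path, contours: dict[str, np.ndarray]) -> None:
    """Write labelled polylines (row/col vertex lists) as JSON."""
    payload = {k: np.asarray(v).tolist() for k, v in contours.items()}
    Path(path).write_text(json.dumps(payload))


def write_manifest(path: str | Path, config: dict, seed: int | None = None) -> None:
    """Write a reproducibility manifest: config, its hash, seed, versions."""
    import zot

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": json.loads(blob),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "versions": {"zot": zot.__version__, "numpy": np.__version__},
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
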