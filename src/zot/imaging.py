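"""Shared 2-D image primitives.

Gradient magnitude, morphological border extraction with outward normals,
sub-pixel resampling (smoothing spline for 1-D profiles, Lanczos for images)
and mm/pixel unit conversion.  All operations assume isotropic pixel spacing;
anisotropic slices must be resampled upstream.

Coordinate convention: (row, col), 0-based, pixel centres at integer
coordinates.  Masks are boolean arrays of pixel centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "ImageSlice",
    "GradientImage",
    "BorderSet",
    "ZoomedImage",
    "gradient_magnitude",
    "extract_border",
    "upsample_1d",
    "lanczos_zoom",
    "mm_to_px",
]

#: 8 compass directions as unit (row, col) vectors, starting east, CCW in
#: image coordinates (row axis points down).
_SQRT2 = np.sqrt(2.0) / 2.0
COMPASS_8 = np.array(
    [
        (0.0, 1.0),
        (-_SQRT2, _SQRT2),
        (-1.0, 0.0),
        (-_SQRT2, -_SQRT2),
        (0.0, -1.0),
        (_SQRT2, -_SQRT2),
        (1.0, 0.0),
        (_SQRT2, _SQRT2),
    ]
)


@dataclass(frozen=True)
class ImageSlice:
    """A 2-D grayscale slice with physical pixel spacing in mm/pixel."""

    pixels: np.ndarray
    spacing: float = 1.0

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("ImageSlice expects a 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel values must be finite")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class GradientImage:
    """Per-pixel gradient magnitude of a parent :class:`ImageSlice`."""

    magnitude: np.ndarray
    spacing: float = 1.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitude.shape


@dataclass
class BorderSet:
    """Ordered border pixels of a mask with outward unit normals.

    ``normals`` holds smoothed distance-transform normals quantised to the
    nearest of 8 compass directions, as used for stripe placement.
    ``thin_roi`` flags masks whose 3x3 erosion is empty, in which case the
    whole mask is its own border.
    """

    coords: np.ndarray  # (n, 2) int, (row, col)
    normals: np.ndarray  # (n, 2) float unit vectors, outward
    thin_roi: bool = False

    def __len__(self) -> int:
        return len(self.coords)


def gradient_magnitude(slc: ImageSlice | np.ndarray, spacing: float = 1.0) -> GradientImage:
    """Gradient-magnitude image from horizontal/vertical 3x3 Sobel responses.

    Uses the unnormalised Sobel kernel ([1,2,1] x [-1,0,1]); borders handled
    by edge replication.  Magnitude is used only relatively downstream, so no
    1/8 normalisation is applied.
    """
    if isinstance(slc, ImageSlice):
        px, spacing = slc.pixels, slc.spacing
    else:
        px = np.asarray(slc, dtype=float)
    if px.shape[0] < 3 or px.shape[1] < 3:
        raise ValueError("image smaller than the 3x3 Sobel kernel")
    gr = ndimage.sobel(px, axis=0, mode="nearest")
    gc = ndimage.sobel(px, axis=1, mode="nearest")
    return GradientImage(np.hypot(gr, gc), spacing)


def _outward_normals(mask: np.ndarray, coords: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Outward normals at ``coords`` from the smoothed signed distance map.

    The signed distance (positive inside) is smoothed over roughly a 3-px
    window; its negated gradient points outward.  Each normal is quantised to
    the nearest of 8 compass directions so diagonal borders get diagonal
    stripes.
    """
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    signed = ndimage.gaussian_filter(inside - outside, sigma)
    gr = ndimage.sobel(signed, axis=0, mode="nearest")
    gc = ndimage.sobel(signed, axis=1, mode="nearest")
    vec = -np.stack([gr[coords[:, 0], coords[:, 1]], gc[coords[:, 0], coords[:, 1]]], axis=1)
    norms = np.linalg.norm(vec, axis=1)
    # degenerate (flat) gradient: default to east
    vec[norms == 0] = (0.0, 1.0)
    norms[norms == 0] = 1.0
    vec /= norms[:, None]
    idx = np.argmax(vec @ COMPASS_8.T, axis=1)
    return COMPASS_8[idx].copy()


def extract_border(mask: np.ndarray) -> BorderSet:
    """Morphological border of a mask: the mask minus its 3x3-square erosion.

    The border pixels are returned in raster order with outward normals.  A
    mask that erodes to empty keeps all of its pixels as border and is
    flagged ``thin_roi``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    thin = not eroded.any()
    border = mask if thin else (mask & ~eroded)
    coords = np.argwhere(border)
    normals = _outward_normals(mask, coords)
    return BorderSet(coords=coords, normals=normals, thin_roi=thin)


def upsample_1d(
    profile: np.ndarray, step: float = 0.1, smooth: bool = True, lam: float | None = None
) -> np.ndarray:
    """Resample a 1-D profile on a sub-sample grid of the given step.

    A smoothing spline is fitted to the samples and evaluated on
    ``arange(0, n-1, step)`` inclusive of the last sample, so a step of 0.1
    maps n samples to ``10*(n-1)+1`` values.  The penalty is ``lam`` when
    given, otherwise GCV-selected; ``smooth=False`` interpolates exactly.
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or y.size < 4:
        raise ValueError("need at least 4 samples to upsample")
    if not 0 < step < 1:
        raise ValueError("step must lie in (0, 1)")
    x = np.arange(y.size, dtype=float)
    grid = np.linspace(0.0, y.size - 1.0, round((y.size - 1) / step) + 1)
    if np.ptp(y) == 0:  # constant profile: spline solver not needed
        return np.full(grid.size, y[0])
    if not smooth:
        lam = 0.0
    spline = make_smoothing_spline(x, y, lam=lam)
    return np.asarray(spline(grid))


@dataclass
class ZoomedImage:
    """A Lanczos-upsampled image that can be sampled at original coordinates.

    ``sample`` does bilinear lookup on the fine grid, with coordinates given
    in the *original* pixel frame; out-of-bounds positions are clamped (edge
    replication).
    """

    fine: np.ndarray
    factor: int

    def sample(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        r = np.clip(np.asarray(rows, float) * self.factor, 0, self.fine.shape[0] - 1)
        c = np.clip(np.asarray(cols, float) * self.factor, 0, self.fine.shape[1] - 1)
        r0 = np.floor(r).astype(int)
        c0 = np.floor(c).astype(int)
        r1 = np.minimum(r0 + 1, self.fine.shape[0] - 1)
        c1 = np.minimum(c0 + 1, self.fine.shape[1] - 1)
        fr = r - r0
        fc = c - c0
        f = self.fine
        return (
            f[r0, c0] * (1 - fr) * (1 - fc)
            + f[r1, c0] * fr * (1 - fc)
            + f[r0, c1] * (1 - fr) * fc
            + f[r1, c1] * fr * fc
        )


def lanczos_zoom(image: np.ndarray, step: float = 0.1) -> ZoomedImage:
    """Upsample an image by 1/step using Lanczos resampling.

    The fine grid is aligned so that fine index ``i`` sits at original
    coordinate ``i*step`` (pixel centres preserved), matching the sub-pixel
    grid used for the gradient profiles.
    """
    img = np.asarray(image, dtype=np.float32)
    factor = round(1.0 / step)
    h, w = img.shape
    # Pad by one replicated pixel so that PIL's area-based alignment error at
    # the frame is negligible, then crop back to the centre-aligned grid.
    pad = np.pad(img, 1, mode="edge")
    target = (pad.shape[1] * factor, pad.shape[0] * factor)
    fine = np.asarray(
        Image.fromarray(pad, mode="F").resize(target, resample=Image.LANCZOS),
        dtype=float,
    )
    # PIL maps source centre (i+0.5)/n -> dest centre (j+0.5)/(n*factor);
    # source coordinate x lands at dest index x*factor + (factor-1)/2 in the
    # padded frame, i.e. (x+1)*factor + (factor-1)/2 pre-crop.
    off = factor + (factor - 1) // 2
    fine = fine[off : off + (h - 1) * factor + 1, off : off + (w - 1) * factor + 1]
    return ZoomedImage(fine=fine, factor=factor)


def mm_to_px(length_mm: float, spacing: float) -> int:
    """Convert a physical length to pixels, rounded, floored at 1."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    return max(1, round(length_mm / spacing))
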