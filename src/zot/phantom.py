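"""Synthetic lesion phantoms with known ground-truth transition bands.

Two phantom families are emulated: near-circular small nodules with shaded
(ramped) borders on noisy parenchyma, as hepatocellular carcinoma appears on
contrast CT, and larger jagged lesions with concavities and adjacent bright
confounder structures, as rectal tumours appear on MRI.  Every phantom
carries the nominal tumour mask and the exact annular transition band, so
the adaptive transition-zone detector can be validated without any clinical
data.  A Gaussian labelled-cohort generator provides feature tables for the
machine-learning protocols.

Intensity model: the lesion interior sits at ``core_level``, the background
at ``background_level``, and intensity ramps between the two across an
annulus of radial width ``transition_width`` centred on the nominal lesion
contour (linear ramp by default, logistic optionally).  Noise is added after
ramp construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import ImageSlice

__all__ = ["PhantomSpec", "PhantomSample", "ConfounderSpec", "make_phantom", "make_labeled_cohort"]


@dataclass(frozen=True)
class ConfounderSpec:
    """An adjacent bright structure outside the lesion.

    ``offset_mm`` is the distance from the lesion centre along ``angle``
    (radians); the confounder is a disk of ``radius_mm`` at ``level``.
    """

    offset_mm: float
    radius_mm: float
    level: float
    angle: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic lesion slice."""

    shape_kind: str = "disk"  # disk | jagged
    image_size: tuple[int, int] = (128, 128)
    pixel_spacing: float = 1.0  # mm / pixel
    lesion_radius: float = 15.0  # mm
    jaggedness: float = 0.0  # radial perturbation amplitude (fraction of R)
    concavity_count: int = 0
    transition_width: float = 4.0  # mm, ground-truth ramp width
    core_level: float = 140.0
    background_level: float = 100.0
    band_profile: str = "linear"  # linear | sigmoid
    noise_sd: float = 2.0
    noise_model: str = "gaussian"  # gaussian | poisson
    confounder: ConfounderSpec | None = None
    phases: int = 1
    phase_offsets: tuple[float, ...] = (0.0, -10.0)  # added to core_level per phase
    seed: int = 0

    def __post_init__(self):
        if self.shape_kind not in ("disk", "jagged"):
            raise ValueError(f"unknown shape_kind {self.shape_kind!r}")
        if self.transition_width <= 0:
            raise ValueError("transition_width must be > 0")
        if self.lesion_radius <= self.transition_width / 2:
            raise ValueError("lesion_radius must exceed transition_width/2")
        if self.phases not in (1, 2):
            raise ValueError("phases must be 1 or 2")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class PhantomSample:
    """One generated phantom: per-phase slices, nominal mask, truth band."""

    slices: list[ImageSlice]
    tumour_mask: np.ndarray
    truth_band: np.ndarray
    spec: PhantomSpec

    @property
    def slice(self) -> ImageSlice:
        return self.slices[0]


def _nominal_radius(theta: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Lesion radius (mm) as a function of polar angle."""
    r = np.full_like(theta, spec.lesion_radius, dtype=float)
    if spec.shape_kind == "jagged" and spec.jaggedness > 0:
        # low-order harmonics with seeded phases; amplitudes decay with order
        for i, k in enumerate((3, 5, 7)):
            phi = rng.uniform(0, 2 * np.pi)
            r += spec.lesion_radius * spec.jaggedness / (i + 1) * np.sin(k * theta + phi)
    return r


def make_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate a phantom sample from its spec (bit-reproducible by seed)."""
    h, w = spec.image_size
    geom_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    noise_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))

    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rows, cols = np.mgrid[0:h, 0:w]
    dy = (rows - cy) * spec.pixel_spacing
    dx = (cols - cx) * spec.pixel_spacing
    theta = np.arctan2(dy, dx)
    rad = np.hypot(dy, dx)

    r_border = _nominal_radius(theta, spec, geom_rng)
    if np.max(r_border) + spec.transition_width / 2 >= min(cy, cx) * spec.pixel_spacing:
        raise ValueError("lesion (plus transition band) does not fit in the image")

    mask = rad <= r_border  # nominal interior before concavities
    if spec.concavity_count > 0:
        for _ in range(spec.concavity_count):
            ang = geom_rng.uniform(0, 2 * np.pi)
            bite_r = geom_rng.uniform(0.15, 0.3) * spec.lesion_radius
            bcy = cy + spec.lesion_radius / spec.pixel_spacing * np.sin(ang)
            bcx = cx + spec.lesion_radius / spec.pixel_spacing * np.cos(ang)
            bite = np.hypot((rows - bcy), (cols - bcx)) * spec.pixel_spacing <= bite_r
            mask &= ~bite
        mask = _largest_component(mask)

    # signed distance to the (possibly carved) nominal contour, mm,
    # positive outside the lesion
    if spec.shape_kind == "disk" and spec.concavity_count == 0:
        signed = rad - r_border  # analytic, sub-pixel exact
    else:
        inside = ndimage.distance_transform_edt(mask, sampling=spec.pixel_spacing)
        outside = ndimage.distance_transform_edt(~mask, sampling=spec.pixel_spacing)
        signed = outside - inside

    half = spec.transition_width / 2.0
    truth_band = np.abs(signed) <= half

    # ramp from core (signed=-half) to background (signed=+half)
    t = np.clip((signed + half) / spec.transition_width, 0.0, 1.0)
    if spec.band_profile == "sigmoid":
        t = 1.0 / (1.0 + np.exp(-8.0 * (t - 0.5)))

    slices: list[ImageSlice] = []
    for p in range(spec.phases):
        core = spec.core_level + (spec.phase_offsets[p] if spec.phases > 1 else 0.0)
        img = core + (spec.background_level - core) * t
        if spec.confounder is not None:
            cf = spec.confounder
            ccy = cy + cf.offset_mm / spec.pixel_spacing * np.sin(cf.angle)
            ccx = cx + cf.offset_mm / spec.pixel_spacing * np.cos(cf.angle)
            cdist = np.hypot(rows - ccy, cols - ccx) * spec.pixel_spacing
            if np.any((cdist <= cf.radius_mm) & (signed < half)):
                raise ValueError("confounder overlaps the lesion or its transition band")
            # 1 mm soft edge so the confounder has its own gradient shell
            ct = np.clip((cdist - cf.radius_mm) / 1.0 + 1.0, 0.0, 1.0)
            img = img * ct + cf.level * (1.0 - ct)
        if spec.noise_sd > 0:
            if spec.noise_model == "gaussian":
                img = img + noise_rng.normal(0.0, spec.noise_sd, size=img.shape)
            elif spec.noise_model == "poisson":
                # count scaling chosen so the background-level sd is noise_sd
                c = max(spec.background_level, 1.0) / spec.noise_sd**2
                img = noise_rng.poisson(np.clip(img, 0, None) * c) / c
            else:
                raise ValueError(f"unknown noise_model {spec.noise_model!r}")
        slices.append(ImageSlice(img, spec.pixel_spacing))

    return PhantomSample(slices=slices, tumour_mask=mask, truth_band=truth_band, spec=spec)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def confounder_mask(sample: PhantomSample) -> np.ndarray:
    """Boolean mask of the confounder disk of a phantom (empty if none)."""
    spec = sample.spec
    h, w = spec.image_size
    if spec.confounder is None:
        return np.zeros((h, w), dtype=bool)
    cf = spec.confounder
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rows, cols = np.mgrid[0:h, 0:w]
    ccy = cy + cf.offset_mm / spec.pixel_spacing * np.sin(cf.angle)
    ccx = cx + cf.offset_mm / spec.pixel_spacing * np.cos(cf.angle)
    return np.hypot(rows - ccy, cols - ccx) * spec.pixel_spacing <= cf.radius_mm


def with_confounder(
    spec: PhantomSpec,
    gap_mm: float = 2.0,
    radius_mm: float = 4.0,
    level: float = 150.0,
    angle: float = 0.0,
) -> PhantomSpec:
    """Attach a confounder just outside the lesion's transition band.

    The confounder disk is pushed out along ``angle`` until its near edge
    clears the outer edge of the transition band by ``gap_mm`` everywhere
    (checked against the distance transform of the whole lesion mask, so
    concave stretches cannot shrink the clearance) — yet stays adjacent
    enough that a fixed-radius rim of a few mm sweeps into it.
    """
    import dataclasses

    base = make_phantom(dataclasses.replace(spec, confounder=None))
    h, w = spec.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    dist = ndimage.distance_transform_edt(~base.tumour_mask, sampling=spec.pixel_spacing)
    clearance = radius_mm + spec.transition_width / 2.0 + gap_mm
    for offset in np.arange(spec.lesion_radius * 0.5, min(cy, cx) * spec.pixel_spacing, 0.25):
        r = cy + offset / spec.pixel_spacing * np.sin(angle)
        c = cx + offset / spec.pixel_spacing * np.cos(angle)
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < h and 0 <= ci < w):
            break
        if dist[ri, ci] >= clearance:
            return dataclasses.replace(
                spec,
                confounder=ConfounderSpec(
                    offset_mm=float(offset), radius_mm=radius_mm, level=level, angle=angle
                ),
            )
    raise ValueError("no admissible confounder position along the requested angle")


def make_labeled_cohort(
    n_pos: int,
    n_neg: int,
    effect_size: np.ndarray | float | None = None,
    n_features: int = 10,
    correlation: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian feature table with planted mean shifts on the positive class.

    ``effect_size`` gives per-feature mean shifts in SD units (scalar or
    length-``n_features``); features are unit-variance Gaussians, optionally
    correlated.  Returns a DataFrame with columns ``f000..`` plus ``label``
    (1 = positive).
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class counts must be positive")
    shift = np.zeros(n_features) if effect_size is None else np.broadcast_to(
        np.asarray(effect_size, dtype=float), (n_features,)
    ).copy()
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    if correlation is not None:
        corr = np.asarray(correlation, dtype=float)
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ValueError("correlation matrix must be positive definite") from exc
        X = rng.standard_normal((n, n_features)) @ chol.T
    else:
        X = rng.standard_normal((n, n_features))
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    X[y == 1] += shift
    perm = rng.permutation(n)
    X, y = X[perm], y[perm]
    cols = [f"f{i:03d}" for i in range(n_features)]
    table = pd.DataFrame(X, columns=cols)
    table["label"] = y
    return table
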