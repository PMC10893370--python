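"""First-order radiomics feature generation.

Twelve statistical descriptors are used throughout: Shannon entropy (E),
mean (mu), standard deviation (sigma), median (M), median absolute
deviation (MAD), skewness (S), kurtosis (K), uniformity (U), interquartile
range (IQR), coefficient of variation (CV), and the mean (mu90) and median
(M90) of the last decile.  The first ten are also computed locally, pixel
by pixel over a small window clipped to the ROI, producing parametric maps;
the twelve descriptors of each of the ten maps (120) plus the twelve
descriptors of the raw ROI intensities (12) give the 132 features of a
transition-region analysis on one channel.  Tumour-core analysis uses the
ten grey-level maps only (120 features, no raw set).

For dual-phase studies the per-phase features are complemented by six
volume features and by the signed relative change (RCS) between the phases
of every per-phase feature:

    RCS = |fA - fV| / |mean(fA, fV)| * sgn(fA - fV)

which is antisymmetric in its arguments and scale-invariant.

Conventions recorded in feature metadata: entropy in bits over 64
equal-width bins spanning the sample min-max; kurtosis is the non-excess
(Pearson) standardised fourth moment; skewness the standardised third
moment; the last decile is the values at or above the 90th percentile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import ImageSlice, gradient_magnitude

__all__ = [
    "DESCRIPTOR_NAMES",
    "MAP_DESCRIPTOR_NAMES",
    "StudyConfig",
    "descriptors",
    "local_maps",
    "region_features",
    "tumour_features",
    "rcs",
    "volume_features",
    "pool_feature_names",
    "assemble_pool",
    "CONVENTIONS",
]

DESCRIPTOR_NAMES = ("E", "mu", "sigma", "M", "MAD", "S", "K", "U", "IQR", "CV", "mu90", "M90")
#: the first ten descriptors, the ones turned into local parametric maps
MAP_DESCRIPTOR_NAMES = DESCRIPTOR_NAMES[:10]

N_BINS = 64

CONVENTIONS = {
    "entropy": "Shannon, bits, 64 equal-width bins over sample min-max",
    "uniformity": "sum of squared bin probabilities, same binning as entropy",
    "skewness": "standardised third central moment (population)",
    "kurtosis": "non-excess (Pearson) standardised fourth moment; 0 on constant samples",
    "last_decile": "values >= 90th percentile, inclusive",
    "cv": "sigma / |mu|; 0 when mu == 0",
}


def _hist_probs(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if lo == hi:
        return np.array([1.0])
    counts, _ = np.histogram(v, bins=N_BINS, range=(lo, hi))
    return counts[counts > 0] / v.size


def descriptors(values: np.ndarray) -> dict[str, float]:
    """The twelve first-order descriptors of a sample of intensities."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty sample")
    mu = float(v.mean())
    sigma = float(v.std())
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    q1, q3 = np.percentile(v, [25, 75])
    p = _hist_probs(v)
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())
    if sigma > 0:
        z = (v - mu) / sigma
        skew = float((z**3).mean())
        kurt = float((z**4).mean())
    else:
        skew = 0.0
        kurt = 0.0
    cv = sigma / abs(mu) if mu != 0 else 0.0
    top = v[v >= np.percentile(v, 90)]
    return {
        "E": entropy,
        "mu": mu,
        "sigma": sigma,
        "M": med,
        "MAD": mad,
        "S": skew,
        "K": kurt,
        "U": uniformity,
        "IQR": float(q3 - q1),
        "CV": float(cv),
        "mu90": float(top.mean()),
        "M90": float(np.median(top)),
    }


def local_maps(
    image: np.ndarray | ImageSlice, roi: np.ndarray, window: int = 3
) -> dict[str, np.ndarray]:
    """Parametric maps of the first ten descriptors over the ROI.

    For each ROI pixel the descriptor is computed on the intensities of the
    centred ``window`` x ``window`` neighbourhood intersected with the ROI.
    Maps are full-size arrays, NaN outside the ROI.  A window larger than
    the ROI bounding box degenerates to a single whole-ROI window (warned).
    """
    px = image.pixels if isinstance(image, ImageSlice) else np.asarray(image, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be odd and positive")
    rr, cc = np.nonzero(roi)
    bbox_h = rr.max() - rr.min() + 1
    bbox_w = cc.max() - cc.min() + 1
    maps = {name: np.full(px.shape, np.nan) for name in MAP_DESCRIPTOR_NAMES}
    if window > max(bbox_h, bbox_w):
        warnings.warn("window larger than ROI bounding box; degenerate single-window maps")
        d = descriptors(px[roi])
        for name in MAP_DESCRIPTOR_NAMES:
            maps[name][roi] = d[name]
        return maps
    half = window // 2
    h, w = px.shape
    for r, c in zip(rr, cc):
        r0, r1 = max(r - half, 0), min(r + half + 1, h)
        c0, c1 = max(c - half, 0), min(c + half + 1, w)
        patch = px[r0:r1, c0:c1]
        sel = roi[r0:r1, c0:c1]
        d = descriptors(patch[sel])
        for name in MAP_DESCRIPTOR_NAMES:
            maps[name][r, c] = d[name]
    return maps


def region_features(
    image: np.ndarray | ImageSlice,
    roi: np.ndarray,
    channel: str = "GL",
    window: int = 3,
    include_global: bool = True,
) -> dict[str, float]:
    """First-order features of one region on one channel.

    Twelve descriptors of each of the ten local maps (120) plus, when
    ``include_global`` is set, the twelve descriptors of the raw ROI
    intensities (12): 132 named features.  Names encode channel, source map
    and descriptor, e.g. ``GM.sigma.K``.
    """
    px = image.pixels if isinstance(image, ImageSlice) else np.asarray(image, dtype=float)
    maps = local_maps(px, roi, window=window)
    feats: dict[str, float] = {}
    for map_name in MAP_DESCRIPTOR_NAMES:
        vals = maps[map_name][np.asarray(roi, dtype=bool)]
        d = descriptors(vals)
        for desc in DESCRIPTOR_NAMES:
            feats[f"{channel}.{map_name}.{desc}"] = d[desc]
    if include_global:
        d = descriptors(px[np.asarray(roi, dtype=bool)])
        for desc in DESCRIPTOR_NAMES:
            feats[f"{channel}.raw.{desc}"] = d[desc]
    return feats


def tumour_features(
    image: np.ndarray | ImageSlice, roi: np.ndarray, window: int = 3
) -> dict[str, float]:
    """Tumour-core features: the 120 map-level grey-level features only."""
    return region_features(image, roi, channel="GL", window=window, include_global=False)


def rcs(fA: float, fV: float, eps: float = 1e-12) -> float:
    """Signed relative change between arterial and venous feature values.

    ``|fA - fV| / |mean(fA, fV)|`` with the sign of ``fA - fV``; NaN when
    the absolute mean vanishes (relative change undefined).
    """
    fbar = abs((fA + fV) / 2.0)
    if fbar <= eps * max(abs(fA), abs(fV), 1e-300):
        return float("nan")
    sign = 1.0 if (fA - fV) >= 0 else -1.0
    return abs(fA - fV) / fbar * sign


def volume_features(
    region_masks: dict[str, np.ndarray],
    tumour_masks: dict[str, np.ndarray],
    spacing: float = 1.0,
    thickness: float = 1.0,
    region_name: str = "region",
) -> dict[str, float]:
    """Six volume features: per-phase region/tumour volumes and their ratios.

    2-D masks are turned into mm^3 as area x nominal slice thickness.
    Phase keys are ``A``/``V``; ratios are arterial over venous, NaN-guarded.
    """
    out: dict[str, float] = {}
    unit = spacing * spacing * thickness
    for name, masks in ((region_name, region_masks), ("tumour", tumour_masks)):
        for phase in ("A", "V"):
            out[f"vol.{name}.{phase}"] = float(np.asarray(masks[phase], bool).sum() * unit)
        va, vv = out[f"vol.{name}.A"], out[f"vol.{name}.V"]
        out[f"vol.{name}.ratio"] = va / vv if vv > 0 else float("nan")
    return out


@dataclass(frozen=True)
class StudyConfig:
    """Which pool of features a study draws on.

    ``region`` is the transition region analysed (``zot``/``trim``) or
    ``tumour``; ``channel`` the image the region features are computed on;
    ``phases`` ``"dual"`` for the arterial/venous design with volumes and
    RCS, ``"single"`` otherwise.
    """

    region: str = "zot"  # zot | trim | tumour
    channel: str = "GM"  # GL | GM
    phases: str = "single"  # single | dual
    include_volumes: bool = True
    include_rcs: bool = True

    def __post_init__(self):
        if self.region not in ("zot", "trim", "tumour"):
            raise ValueError("region must be zot, trim or tumour")
        if self.channel not in ("GL", "GM"):
            raise ValueError("channel must be GL or GM")
        if self.phases not in ("single", "dual"):
            raise ValueError("phases must be single or dual")


def _region_names(region: str, channel: str) -> list[str]:
    names = [
        f"{region}.{channel}.{m}.{d}" for m in MAP_DESCRIPTOR_NAMES for d in DESCRIPTOR_NAMES
    ]
    names += [f"{region}.{channel}.raw.{d}" for d in DESCRIPTOR_NAMES]
    return names


def _tumour_names() -> list[str]:
    return [f"tumour.GL.{m}.{d}" for m in MAP_DESCRIPTOR_NAMES for d in DESCRIPTOR_NAMES]


def pool_feature_names(config: StudyConfig) -> list[str]:
    """Deterministic feature-name list of a study pool (data-independent).

    Dual-phase transition-region pools have 762 names: 132 region features
    per phase, 120 tumour features per phase, 6 volumes and the 252 RCS
    features of every per-phase pair.  Single-phase pools have 132 (region)
    or 120 (tumour) names.
    """
    if config.phases == "single":
        if config.region == "tumour":
            return _tumour_names()
        return _region_names(config.region, config.channel)
    if config.region == "tumour":
        raise ValueError("the dual-phase pool is defined for a transition region")
    base_region = _region_names(config.region, config.channel)
    base_tumour = _tumour_names()
    names: list[str] = []
    for phase in ("A", "V"):
        names += [f"{phase}.{n}" for n in base_region]
    for phase in ("A", "V"):
        names += [f"{phase}.{n}" for n in base_tumour]
    if config.include_volumes:
        for name in (config.region, "tumour"):
            names += [f"vol.{name}.A", f"vol.{name}.V", f"vol.{name}.ratio"]
    if config.include_rcs:
        names += [f"rcs.{n}" for n in base_region + base_tumour]
    return names


def assemble_pool(
    config: StudyConfig,
    inputs: dict,
    spacing: float = 1.0,
    thickness: float = 1.0,
    window: int = 3,
) -> pd.Series:
    """Compute the full feature pool of one sample.

    ``inputs`` maps phase keys (``"A"``, and ``"V"`` for dual) to dicts with
    ``image`` (grey-level slice), ``region_mask`` and ``tumour_mask``.  The
    gradient-magnitude channel is derived here when the study needs it.
    Returns a Series indexed exactly by :func:`pool_feature_names`.
    """
    phases = ("A",) if config.phases == "single" else ("A", "V")
    for ph in phases:
        if ph not in inputs:
            raise ValueError(f"missing phase {ph!r} for {config.phases}-phase config")
    values: dict[str, float] = {}
    per_phase: dict[str, dict[str, float]] = {}
    for ph in phases:
        data = inputs[ph]
        img = np.asarray(data["image"], dtype=float)
        chan_img = gradient_magnitude(img).magnitude if config.channel == "GM" else img
        block: dict[str, float] = {}
        if config.region != "tumour":
            reg = region_features(chan_img, data["region_mask"], config.channel, window)
            block.update({f"{config.region}.{k}": v for k, v in reg.items()})
        if config.region == "tumour" or config.phases == "dual":
            tum = tumour_features(img, data["tumour_mask"], window)
            block.update({f"tumour.{k}": v for k, v in tum.items()})
        per_phase[ph] = block
    if config.phases == "single":
        values.update(per_phase["A"])
    else:
        for ph in phases:
            values.update({f"{ph}.{k}": v for k, v in per_phase[ph].items()})
        if config.include_volumes:
            values.update(
                volume_features(
                    {ph: inputs[ph]["region_mask"] for ph in phases},
                    {ph: inputs[ph]["tumour_mask"] for ph in phases},
                    spacing=spacing,
                    thickness=thickness,
                    region_name=config.region,
                )
            )
        if config.include_rcs:
            for name in per_phase["A"]:
                values[f"rcs.{name}"] = rcs(per_phase["A"][name], per_phase["V"][name])
    names = pool_feature_names(config)
    return pd.Series([values[n] for n in names], index=names, dtype=float)
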