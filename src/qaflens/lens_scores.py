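"""Image-derived lens opacity scores.

Three opacity proxies are extracted from the acquisitions:

* **LQAF** — lens quantitative autofluorescence: the highest central-region
  mean over the 64 slabs of the z-stack, divided by the internal-reference
  mean (a 200 x 18-pixel strip at native resolution).
* **AC-OCT relative reflectivity** — lens-region mean over cornea-region mean
  after min-max normalization of the section to [0, 1].
* **PNS** — Pentacam-style nucleus staging: mean / SD / max density over the
  nucleus mask, with the 0-5 grade given by how many calibrated thresholds
  the mean density reaches (the manufacturer's exact formula is unpublished;
  the grade edges here are calibrated against the generator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import ImageStack


@dataclass
class LensScoreSet:
    lqaf: float
    acoct_reflectivity: float
    pns_grade: int
    pns_mean_density: float
    pns_sd_density: float
    pns_max_density: float


def _check_region(region, shape, name):
    r0, r1, c0, c1 = region
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise ValueError(f"{name} region {region} outside image of shape {shape}")


def compute_lqaf(stack: ImageStack | np.ndarray,
                 center_size_px: tuple = (60, 60),
                 ref_region: tuple = (10, 28, 284, 484),
                 center_region: tuple | None = None,
                 scale: float = 1.0,
                 per_slab_ratio: bool = False,
                 subtract_offset: float = 0.0) -> float:
    """LQAF score of a z-stack.

    The center region defaults to a 60 x 60-pixel square whose top-left corner
    sits at ``floor((dim - 60) / 2)``; an explicit ``center_region`` rectangle
    overrides it.  By default the reference denominator is taken from the slab
    that maximizes the center mean; ``per_slab_ratio=True`` instead maximizes
    the per-slab center/reference ratio.  ``subtract_offset`` optionally
    removes a dark gray-value offset from both means before the ratio.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack, float)
    if data.ndim == 2:
        data = data[None]
    _, H, W = data.shape
    if center_region is None:
        ch, cw = center_size_px
        r0, c0 = (H - ch) // 2, (W - cw) // 2
        center_region = (r0, r0 + ch, c0, c0 + cw)
    _check_region(center_region, (H, W), "center")
    _check_region(ref_region, (H, W), "reference")
    a0, a1, b0, b1 = center_region
    r0, r1, c0, c1 = ref_region
    center = data[:, a0:a1, b0:b1].mean(axis=(1, 2)) - subtract_offset
    ref = data[:, r0:r1, c0:c1].mean(axis=(1, 2)) - subtract_offset
    k = int(np.argmax(center / ref)) if per_slab_ratio else int(np.argmax(center))
    if ref[k] <= 0:
        raise ArithmeticError(
            f"reference-region mean {ref[k]:.3g} is not positive in slab {k}; "
            "cannot normalize")
    return float(scale * center[k] / ref[k])


def compute_acoct_reflectivity(image: np.ndarray, cornea_roi: tuple,
                               lens_roi: tuple, scale: float = 1.0) -> float:
    """Relative lens reflectivity of an AC-OCT section.

    The image is min-max normalized to [0, 1] (white = 1, black = 0); the
    score is ``scale * mean(lens ROI) / mean(cornea ROI)`` on the normalized
    image.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("AC-OCT section must be a 2-D image")
    _check_region(cornea_roi, img.shape, "cornea")
    _check_region(lens_roi, img.shape, "lens")
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        raise ValueError("constant image: min-max normalization undefined")
    norm = (img - lo) / (hi - lo)
    a0, a1, b0, b1 = cornea_roi
    cornea = float(norm[a0:a1, b0:b1].mean())
    if cornea <= 0:
        raise ArithmeticError("cornea ROI mean is not positive after normalization")
    a0, a1, b0, b1 = lens_roi
    return float(scale * norm[a0:a1, b0:b1].mean() / cornea)


def compute_pns(density_map: np.ndarray, nucleus_mask: np.ndarray,
                grade_edges) -> dict:
    """Nucleus density statistics and the 0-5 staging grade.

    ``grade = number of edges <= mean density`` (edges inclusive on the left:
    a mean exactly at edge *k* yields grade *k*).  SD uses the n-1 denominator;
    a single-pixel mask reports SD 0.
    """
    dmap = np.asarray(density_map, dtype=float)
    mask = np.asarray(nucleus_mask, dtype=bool)
    if dmap.shape != mask.shape:
        raise ValueError("density map and nucleus mask shapes differ")
    if not mask.any():
        raise ValueError("nucleus mask is empty")
    edges = np.asarray(grade_edges, dtype=float)
    if edges.size != 5 or np.any(np.diff(edges) <= 0):
        raise ValueError("grade_edges must be 5 strictly increasing thresholds")
    vals = dmap[mask]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return {"grade": int(np.sum(edges <= mean)), "mean": mean,
            "sd": sd, "max": float(vals.max())}
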