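"""Retinal QAF analysis: frame alignment/averaging, internal-reference
normalization, and the QAF8 ring statistic (annulus at 6-8 degrees
eccentricity from the fovea, divided into eight 45-degree segments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import FundusGeometry


@dataclass
class QafMap:
    values: np.ndarray
    geometry: FundusGeometry
    scale_k: float


@dataclass
class Qaf8Result:
    ring_mean: float
    segment_means: np.ndarray   # 8 values, CCW from the image-x axis
    pixel_count: int


def align_and_average(frames: np.ndarray, max_shift: int = 4,
                      exclude_region: tuple | None = None,
                      return_shifts: bool = False):
    """Align frames to the first frame by integer-pixel translation and average.

    The shift of each frame is the integer translation (within ``max_shift``)
    maximizing the Pearson correlation with frame 1 over the overlap area; the
    aligned frames are averaged with overlap-only averaging at the borders
    (each output pixel averages only the frames that cover it).
    ``exclude_region`` masks a rectangle (e.g. the static internal-reference
    strip) out of the shift estimation.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need at least 2 frames of identical size")
    n, H, W = frames.shape
    intervals = _valid_row_intervals(H, max_shift, exclude_region)
    ref = frames[0]
    acc = np.zeros((H, W))
    cnt = np.zeros((H, W))
    shifts = [(0, 0)]
    acc += ref
    cnt += 1.0
    for f in range(1, n):
        dy, dx = _best_shift(ref, frames[f], max_shift, intervals)
        shifts.append((dy, dx))
        # frame content at (r, c) corresponds to reference position (r - dy, c - dx)
        ra0, ra1 = max(0, -dy), min(H, H - dy)
        ca0, ca1 = max(0, -dx), min(W, W - dx)
        acc[ra0:ra1, ca0:ca1] += frames[f, ra0 + dy:ra1 + dy, ca0 + dx:ca1 + dx]
        cnt[ra0:ra1, ca0:ca1] += 1.0
    mean = acc / cnt
    return (mean, shifts) if return_shifts else mean


def _valid_row_intervals(H: int, max_shift: int, exclude_region):
    """Row intervals of the fixed comparison window: the central band
    [max_shift, H - max_shift) minus any excluded rows (expanded by
    ``max_shift`` so no shift can drag excluded pixels into the window)."""
    cut = []
    if exclude_region is not None:
        r0, r1, _, _ = exclude_region
        cut = [(max(0, r0 - max_shift), r1 + max_shift)]
    lo, hi = max_shift, H - max_shift
    intervals = []
    start = lo
    for a, b in sorted(cut):
        if a > start:
            intervals.append((start, min(a, hi)))
        start = max(start, b)
    if start < hi:
        intervals.append((start, hi))
    return [(a, b) for a, b in intervals if b > a]


def _best_shift(ref: np.ndarray, frame: np.ndarray, max_shift: int, intervals):
    """Exhaustive integer-shift search maximizing the Pearson correlation of
    the shifted frame with the reference over a fixed interior window (so
    every candidate shift is compared on identically-sized data)."""
    H, W = ref.shape
    c0, c1 = max_shift, W - max_shift
    blocks = [ref[a:b, c0:c1].ravel() for a, b in intervals]
    a_all = np.concatenate(blocks)
    a_all = a_all - a_all.mean()
    na = a_all @ a_all
    best, best_r = (0, 0), -np.inf
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            b_all = np.concatenate([
                frame[a + dy:b + dy, c0 + dx:c1 + dx].ravel()
                for a, b in intervals])
            b_all = b_all - b_all.mean()
            denom = np.sqrt(na * (b_all @ b_all))
            r = (a_all @ b_all) / denom if denom > 0 else 0.0
            if r > best_r + 1e-12:
                best_r, best = r, (dy, dx)
    return best


def normalize_to_reference(mean_image: np.ndarray, geometry: FundusGeometry,
                           scale_k: float,
                           ref_mean: float | None = None) -> QafMap:
    """Internal-reference normalization:
    ``QAF = scale_k * (GV - zero_gv) / (GV_ref_mean - zero_gv)``.

    A pixel at the dark offset maps to 0; a pixel at the reference mean maps
    to ``scale_k`` (the instrument calibration constant in QAF a.u.).  By
    default the reference mean is read from ``mean_image``; pass ``ref_mean``
    explicitly when the average was content-aligned (alignment displaces the
    static reference strip, so its mean should be taken from the raw frames).
    """
    img = np.asarray(mean_image, dtype=float)
    r0, r1, c0, c1 = geometry.reference_region
    if ref_mean is None:
        ref_mean = float(img[r0:r1, c0:c1].mean())
    if ref_mean <= geometry.zero_gv:
        raise ArithmeticError(
            f"reference mean {ref_mean:.3g} does not exceed the dark offset "
            f"{geometry.zero_gv:.3g}")
    values = scale_k * (img - geometry.zero_gv) / (ref_mean - geometry.zero_gv)
    return QafMap(values=values, geometry=geometry, scale_k=scale_k)


def ring_masks(geometry: FundusGeometry, shape: tuple | None = None):
    """Boolean ring mask (6 <= eccentricity < 8 degrees) and the 0-7 segment
    index per pixel (45-degree sectors, counter-clockwise from the image-x
    axis with image rows pointing down)."""
    H, W = shape if shape is not None else geometry.image_size_px
    fr, fc = geometry.fovea_center_px
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    dy = -(rr - fr)          # CCW angles in display orientation
    dx = cc - fc
    ecc = np.hypot(dy, dx) * geometry.degrees_per_px
    ring = (ecc >= 6.0) & (ecc < 8.0)
    ang = np.degrees(np.arctan2(dy, dx)) % 360.0
    seg = np.minimum((ang / 45.0).astype(int), 7)
    return ring, seg


def sample_qaf8(qaf_map: QafMap) -> Qaf8Result:
    """Mean QAF over the 6-8 degree ring and its eight 45-degree segments.

    The ring mean is the mean over all ring pixels — equivalently the
    pixel-count-weighted mean of the segment means.
    """
    values = qaf_map.values
    geom = qaf_map.geometry
    H, W = values.shape
    fr, fc = geom.fovea_center_px
    r_out = 8.0 / geom.degrees_per_px
    if (fr - r_out < 0 or fr + r_out > H - 1 or fc - r_out < 0
            or fc + r_out > W - 1):
        raise ValueError(
            f"the 8-degree ring (radius {r_out:.1f} px around fovea "
            f"({fr:.1f}, {fc:.1f})) extends outside the {H}x{W} image")
    ring, seg = ring_masks(geom, (H, W))
    seg_means = np.array([values[ring & (seg == s)].mean() for s in range(8)])
    return Qaf8Result(ring_mean=float(values[ring].mean()),
                      segment_means=seg_means,
                      pixel_count=int(ring.sum()))


def qaf8_from_frames(frames: np.ndarray, geometry: FundusGeometry,
                     scale_k: float, max_shift: int = 4) -> Qaf8Result:
    """Full retinal pipeline: align/average the frame series (masking the
    static reference strip out of the shift estimation), normalize to the
    internal reference, and sample the QAF8 ring."""
    mean = align_and_average(frames, max_shift=max_shift,
                             exclude_region=geometry.reference_region)
    r0, r1, c0, c1 = geometry.reference_region
    ref_mean = float(np.asarray(frames, dtype=float)[:, r0:r1, c0:c1].mean())
    return sample_qaf8(normalize_to_reference(mean, geometry, scale_k,
                                              ref_mean=ref_mean))
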