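"""Synthetic-eye generator.

Emulates the optical structure that makes lens opacity depress quantitative
fundus autofluorescence (QAF): short-wavelength excitation light (488 nm) and
the emission band are attenuated by the crystalline lens on their way through
the eye, while the instrument-internal fluorescent reference — excited and
captured inside the device — is untouched.  Normalizing the fundus signal to
that reference therefore under-estimates true retinal autofluorescence in
opacified eyes, which is the effect the correction models downstream are
built to undo.

The generator produces, per subject: an age; a systemic-aging latent factor
shared between lens fluorophore accumulation, lens optical density and
retinal autofluorescence; a ground-truth lens profile; a ground-truth retinal
QAF level; and rendered acquisitions for all four modalities (64-slab LQAF
z-stack, AC-OCT section, Scheimpflug densitometry map, 12-frame QAF series).
A fast analytic ("tabular") mode applies the same measurement equations
without rasterizing images.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .config import EXCITATION_NM, GeneratorConfig, StudyConfig

PATTERNS = ("nuclear", "cortical", "posterior_subcapsular")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LensProfile:
    """Ground-truth state of one crystalline (or artificial) lens."""

    optical_density_488: float      # base-10 absorbance at 488 nm
    fluorophore_level: float        # intrinsic lens fluorescence, a.u.
    pattern: str                    # nuclear | cortical | posterior_subcapsular | clear
    axial_position_mm: float        # lens center within the 8 mm LQAF range

    def __post_init__(self):
        if self.pattern not in PATTERNS + ("clear",):
            raise ValueError(f"unknown opacity pattern {self.pattern!r}")
        if self.optical_density_488 < 0 or self.fluorophore_level < 0:
            raise ValueError("optical density and fluorophore level must be >= 0")
        if self.pattern == "clear" and (
                self.optical_density_488 != 0 or self.fluorophore_level != 0):
            raise ValueError("a clear (pseudophakic) lens has zero density and fluorescence")

    @classmethod
    def clear(cls) -> "LensProfile":
        return cls(0.0, 0.0, "clear", 4.2)


@dataclass
class FundusGeometry:
    """Pixel grid, field of view and internal-reference location of a frame."""

    image_size_px: tuple            # (rows, cols)
    field_degrees: float
    fovea_center_px: tuple          # (row, col)
    reference_region: tuple         # (r0, r1, c0, c1), half-open
    zero_gv: float = 0.0

    @property
    def degrees_per_px(self) -> float:
        return self.field_degrees / self.image_size_px[0]

    @classmethod
    def default(cls, size: int = 768, field_degrees: float = 30.0,
                zero_gv: float = 0.0) -> "FundusGeometry":
        """Instrument-native geometry (768 px / 30 deg) or a scaled version.

        The reference strip scales with the frame: at 768 px it is the
        200 x 18-pixel region near the top of the image.
        """
        s = size / 768.0
        r0 = max(1, round(10 * s))
        nr = max(2, round(18 * s))
        nc = max(4, round(200 * s))
        c0 = (size - nc) // 2
        return cls((size, size), field_degrees, (size / 2.0, size / 2.0),
                   (r0, r0 + nr, c0, c0 + nc), zero_gv)

    def validate(self) -> None:
        r0, r1, c0, c1 = self.reference_region
        H, W = self.image_size_px
        if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
            raise ValueError("reference_region outside the image")
        # the reference strip must not intersect the 6-8 degree ring
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        ecc = np.hypot(rr - self.fovea_center_px[0],
                       cc - self.fovea_center_px[1]) * self.degrees_per_px
        if np.any((ecc >= 6.0) & (ecc < 8.0)):
            raise ValueError("reference_region intersects the 6-8 degree ring")


@dataclass
class ImageStack:
    """A (slabs x rows x cols) grayscale acquisition; 1 slab for 2-D modalities."""

    data: np.ndarray
    bit_depth: int = 16
    pixel_pitch_mm: float = 0.125   # axial pitch: 8 mm / 64 slabs for LQAF

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be 2-D or 3-D")
        if np.any(self.data < 0):
            raise ValueError("gray values must be >= 0")


@dataclass
class SubjectRecord:
    """One eye of the synthetic cohort (pre-surgery visit; post fields for the
    surgery subset)."""

    subject_id: str
    age: float
    phakic: bool
    lens: LensProfile
    scores: dict = field(default_factory=dict)
    qaf8_pre: Optional[float] = None
    qaf8_post: Optional[float] = None
    qaf8_true: Optional[float] = None
    # generator-only ground truth used to render consistent images
    lqaf_target: Optional[float] = None
    acoct_target: Optional[float] = None
    latent_aging: Optional[float] = None
    od_latent: Optional[float] = None


# ---------------------------------------------------------------------------
# random-stream plumbing
# ---------------------------------------------------------------------------

def subject_rng(seed: int, subject_id: str, context: str = "") -> np.random.Generator:
    """Deterministic per-subject substream: stable hash of the subject id (and a
    context tag) mixed into the root seed, so cohorts can be generated or
    re-rendered in any order."""
    tag = zlib.crc32(f"{subject_id}:{context}".encode())
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, tag])))


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _poisson_noise(img: np.ndarray, ppg: float, rng: np.random.Generator,
                   noise_scale: float) -> np.ndarray:
    """Poisson-like shot noise: gray values converted to photon counts at
    ``ppg`` photons per gray value; ``noise_scale`` rescales the variance and
    0 disables noise entirely."""
    if noise_scale <= 0:
        return img
    gain = ppg / noise_scale ** 2
    return rng.poisson(np.maximum(img, 0.0) * gain) / gain


# ---------------------------------------------------------------------------
# lens model
# ---------------------------------------------------------------------------

def generate_lens(age: float, rng: np.random.Generator,
                  params: GeneratorConfig | None = None,
                  latent: float | None = None) -> LensProfile:
    """Draw a ground-truth lens for a subject of the given age.

    Mean optical density follows a softplus curve of age (near zero in young
    eyes, roughly linear beyond the onset age) with multiplicative lognormal
    individual noise; the lognormal's normal latent loads partly on the
    subject's systemic-aging factor ``latent``.  Fluorophore level is set from
    the same latent structure via the LQAF-score target (see
    :func:`generate_subject`); here it is derived directly so that the
    standalone operation is self-contained.
    """
    cfg = params or GeneratorConfig()
    if not (18.0 <= age <= 100.0):
        raise ValueError(f"age {age} outside the supported range [18, 100]")
    if latent is None:
        latent = float(rng.standard_normal()) if cfg.noise_scale > 0 else 0.0
    rho = cfg.od_latent_loading
    z = float(rng.standard_normal()) if cfg.noise_scale > 0 else 0.0
    u = rho * latent + np.sqrt(max(0.0, 1 - rho ** 2)) * z
    mean_curve = cfg.od_scale * _softplus(cfg.od_slope * (age - cfg.od_onset))
    s = cfg.od_sigma * cfg.noise_scale
    d = float(mean_curve * np.exp(s * u - s ** 2 / 2.0))
    fl = _fluorophore_from_target(_lqaf_target(age, latent, rng, cfg), d, cfg)
    axial = float(np.clip(cfg.lens_axial_mean_mm
                          + cfg.lens_axial_sd_mm * (rng.standard_normal()
                                                    if cfg.noise_scale > 0 else 0.0),
                          1.0, 7.0))
    pattern = PATTERNS[int(rng.choice(len(PATTERNS), p=np.asarray(cfg.pattern_probs)
                                      / np.sum(cfg.pattern_probs)))]
    return LensProfile(d, fl, pattern, axial)


def lens_transmission(lens: LensProfile, wavelength_nm: float) -> float:
    """Fraction of light transmitted by the lens at a given wavelength.

    Scattering by lens opacities is strongest at short wavelengths (Rayleigh:
    intensity ~ wavelength^-4), so the optical density scales as
    (488/lambda)^4 relative to its value at the 488 nm excitation line:
    ``T(lambda) = 10**(-d * (488/lambda)**4)``.
    """
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    d = lens.optical_density_488 * (EXCITATION_NM / wavelength_nm) ** 4
    return float(10.0 ** (-d))


def total_transmission(lens: LensProfile, cfg: GeneratorConfig) -> float:
    """Round-trip transmission: excitation in at 488 nm, emission out at the
    effective emission wavelength (mid emission band by default)."""
    if not cfg.attenuation_enabled:
        return 1.0
    return lens_transmission(lens, EXCITATION_NM) * lens_transmission(lens, cfg.emission_nm)


# ---------------------------------------------------------------------------
# score-target model (shared by tabular and rendered modes)
# ---------------------------------------------------------------------------

def _lqaf_target(age: float, latent: float, rng: np.random.Generator,
                 cfg: GeneratorConfig) -> float:
    age_std = (age - cfg.age_center) / cfg.age_scale
    eps = float(rng.standard_normal()) if cfg.noise_scale > 0 else 0.0
    z = cfg.lqaf_mu + cfg.lqaf_latent_scale * (
        cfg.lqaf_w_age * age_std + cfg.lqaf_w_latent * latent + cfg.lqaf_w_noise * eps)
    return cfg.lqaf_lo + (cfg.lqaf_hi - cfg.lqaf_lo) * _sigmoid(z)


def _fluorophore_from_target(target: float, d: float, cfg: GeneratorConfig) -> float:
    """Invert the noise-free LQAF measurement equation so the rendered stack
    scores back to ``target``: score = scale*(bg + gain*(fl + w*d))/ref."""
    offset = cfg.lqaf_score_scale * cfg.lqaf_bg_gv / cfg.lqaf_ref_gv
    fl = (target - offset - cfg.lqaf_scatter_weight * d)
    return float(max(fl, 0.0))


def _acoct_target(d: float, rng: np.random.Generator, cfg: GeneratorConfig) -> float:
    eps = float(rng.standard_normal()) if cfg.noise_scale > 0 else 0.0
    z = (cfg.acoct_gain * (np.log10(d + cfg.acoct_log_offset) - cfg.acoct_center)
         + cfg.acoct_noise_sd * eps)
    return cfg.acoct_lo + (cfg.acoct_hi - cfg.acoct_lo) * _sigmoid(z)


# ---------------------------------------------------------------------------
# LQAF z-stack
# ---------------------------------------------------------------------------

def lqaf_geometry(rows: int = 768, cols: int = 768) -> dict:
    """Pixel regions of the LQAF acquisition: centered square measuring region
    and internal-reference strip, scaled from the native 60x60 / 200x18 at 768."""
    ch = max(2, round(60 * rows / 768))
    cw = max(2, round(60 * cols / 768))
    r0 = (rows - ch) // 2
    c0 = (cols - cw) // 2
    nr = max(2, round(18 * rows / 768))
    nc = max(4, round(200 * cols / 768))
    rr0 = max(1, round(10 * rows / 768))
    cc0 = (cols - nc) // 2
    return {"center_region": (r0, r0 + ch, c0, c0 + cw),
            "ref_region": (rr0, rr0 + nr, cc0, cc0 + nc)}


def render_lqaf_stack(lens: LensProfile, rng: np.random.Generator,
                      cfg: GeneratorConfig | None = None,
                      rows: int = 64, cols: int = 64) -> ImageStack:
    """Render the 64-slab LQAF acquisition (8 mm axial range).

    The lens appears as a central disk whose intensity follows a Gaussian
    axial profile peaking at the slab nearest the lens center; peak intensity
    is proportional to the fluorophore level plus a configurable
    scatter-derived term proportional to optical density.  The internal
    reference strip has fixed intensity, independent of the lens.
    """
    cfg = cfg or GeneratorConfig()
    n = cfg.lqaf_n_slabs
    pitch = cfg.lqaf_depth_mm / n
    z = (np.arange(n) + 0.5) * pitch
    axial = np.exp(-0.5 * ((z - lens.axial_position_mm) / cfg.lqaf_axial_sigma_mm) ** 2)
    signal = cfg.lqaf_gain_gv * (lens.fluorophore_level
                                 + cfg.lqaf_scatter_weight * lens.optical_density_488)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    disk = (np.hypot(rr - (rows - 1) / 2.0, cc - (cols - 1) / 2.0)
            <= 0.35 * min(rows, cols)).astype(float)
    stack = cfg.lqaf_bg_gv + signal * axial[:, None, None] * disk[None]
    geo = lqaf_geometry(rows, cols)
    r0, r1, c0, c1 = geo["ref_region"]
    stack[:, r0:r1, c0:c1] = cfg.lqaf_ref_gv
    stack = _poisson_noise(stack, cfg.ppg_lqaf, rng, cfg.noise_scale)
    return ImageStack(stack, bit_depth=16, pixel_pitch_mm=pitch)


# ---------------------------------------------------------------------------
# AC-OCT section
# ---------------------------------------------------------------------------

def render_acoct_section(lens: LensProfile, rng: np.random.Generator,
                         cfg: GeneratorConfig | None = None,
                         shape: tuple = (96, 128),
                         target: float | None = None):
    """Render an axial anterior-chamber OCT section.

    Returns ``(image, rois)`` where ``rois`` holds the cornea and lens
    rectangles.  The corneal band has fixed gray level across subjects; the
    lens-region level increases monotonically with optical density (through
    the reflectivity target, a saturating function of log density).
    """
    cfg = cfg or GeneratorConfig()
    H, W = shape
    if target is None:
        target = _acoct_target(lens.optical_density_488, rng, cfg) \
            if lens.pattern != "clear" else cfg.acoct_lo
    img = np.zeros((H, W), dtype=float)
    cornea = (round(0.08 * H), round(0.16 * H), round(0.15 * W), round(0.85 * W))
    lens_roi = (round(0.35 * H), round(0.75 * H), round(0.30 * W), round(0.70 * W))
    img[cornea[0]:cornea[1], cornea[2]:cornea[3]] = cfg.acoct_cornea_gv
    img[lens_roi[0]:lens_roi[1], lens_roi[2]:lens_roi[3]] = (
        cfg.acoct_cornea_gv * target / cfg.acoct_score_scale)
    img = _poisson_noise(img, cfg.ppg_acoct, rng, cfg.noise_scale)
    return img, {"cornea": cornea, "lens": lens_roi}


# ---------------------------------------------------------------------------
# Scheimpflug densitometry
# ---------------------------------------------------------------------------

def _scheimpflug_template(pattern: str, shape: tuple) -> np.ndarray:
    """Unit-amplitude spatial layout of each cataract type: nuclear = central
    blob, cortical = peripheral spokes, posterior subcapsular = thin posterior
    layer."""
    H, W = shape
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    y = (rr - (H - 1) / 2.0) / (H / 2.0)
    x = (cc - (W - 1) / 2.0) / (W / 2.0)
    r = np.hypot(x, y)
    if pattern == "nuclear":
        return np.exp(-0.5 * (r / 0.28) ** 2)
    if pattern == "cortical":
        theta = np.arctan2(y, x)
        spokes = 0.5 * (1 + np.cos(8 * theta))
        return spokes * np.clip((r - 0.25) / 0.45, 0, 1) * (r < 0.95)
    if pattern == "posterior_subcapsular":
        return np.exp(-0.5 * ((y - 0.55) / 0.08) ** 2) * (np.abs(x) < 0.5)
    return np.zeros(shape)


def nucleus_mask(shape: tuple) -> np.ndarray:
    H, W = shape
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    y = (rr - (H - 1) / 2.0) / (H / 2.0)
    x = (cc - (W - 1) / 2.0) / (W / 2.0)
    return (np.hypot(x, y / 0.8) < 0.45)


def render_scheimpflug_densitometry(lens: LensProfile, rng: np.random.Generator,
                                    cfg: GeneratorConfig | None = None,
                                    shape: tuple = (96, 96)):
    """Render a Scheimpflug lens-density map; returns ``(map, mask)`` with the
    nucleus mask used for PNS statistics."""
    cfg = cfg or GeneratorConfig()
    i = PATTERNS.index(lens.pattern) if lens.pattern in PATTERNS else None
    amp = 0.0 if i is None else (cfg.pns_gain * lens.optical_density_488
                                 * cfg.pattern_factors[i])
    dmap = amp * _scheimpflug_template(lens.pattern, shape)
    dmap = _poisson_noise(dmap + 0.5, cfg.ppg_scheimpflug, rng, cfg.noise_scale) - 0.5
    return np.maximum(dmap, 0.0), nucleus_mask(shape)


def scheimpflug_nucleus_stats(pattern: str, shape: tuple,
                              cfg: GeneratorConfig) -> tuple:
    """Noise-free (mean, sd, max) of the unit-density template over the nucleus
    mask — the analytic measurement model used in tabular mode."""
    i = PATTERNS.index(pattern) if pattern in PATTERNS else None
    if i is None:
        return 0.0, 0.0, 0.0
    t = _scheimpflug_template(pattern, shape)[nucleus_mask(shape)]
    f = cfg.pns_gain * cfg.pattern_factors[i]
    return f * float(t.mean()), f * float(t.std(ddof=1)), f * float(t.max())


def pns_grade_from_mean(mean_density: float, cfg: GeneratorConfig) -> int:
    return int(np.sum(np.asarray(cfg.pns_grade_edges) <= mean_density))


# ---------------------------------------------------------------------------
# ground-truth retinal QAF map and the 12-frame acquisition
# ---------------------------------------------------------------------------

def generate_truth_map(level: float, geometry: FundusGeometry,
                       rng: np.random.Generator,
                       cfg: GeneratorConfig | None = None) -> np.ndarray:
    """Smooth radial ground-truth QAF field with a dark optic-disc ellipse and
    dark vessel strokes, rescaled so its 6-8 degree ring mean equals ``level``
    exactly."""
    cfg = cfg or GeneratorConfig()
    H, W = geometry.image_size_px
    fr, fc = geometry.fovea_center_px
    dpp = geometry.degrees_per_px
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    ecc = np.hypot(rr - fr, cc - fc) * dpp
    base = (1.0 - 0.72 * np.exp(-0.5 * (ecc / 2.0) ** 2)) \
        * (1.0 + 0.10 * np.exp(-0.5 * ((ecc - 8.0) / 5.0) ** 2))
    # optic disc at ~13 degrees on the horizontal meridian
    disc = np.hypot((cc - fc - 13.0 / dpp) / (2.2 / dpp),
                    (rr - fr) / (1.7 / dpp)) < 1.0
    base = np.where(disc, 0.12 * base, base)
    # a few dark vessel strokes radiating from the disc
    n_vessels = 4
    for k in range(n_vessels):
        ang = np.pi * (0.55 + 0.3 * k / n_vessels) * (1 if k % 2 else -1) \
            + (0.08 * rng.standard_normal() if cfg.noise_scale > 0 else 0.0)
        p0 = np.array([fr, fc + 13.0 / dpp])
        p1 = p0 + (18.0 / dpp) * np.array([np.sin(ang), np.cos(ang)])
        dist = _dist_to_segment(rr, cc, p0, p1)
        base *= 1.0 - 0.35 * np.exp(-0.5 * (dist / (0.25 / dpp)) ** 2)
    ring = (ecc >= 6.0) & (ecc < 8.0)
    base *= level / base[ring].mean()
    return base


def _dist_to_segment(rr, cc, p0, p1):
    v = p1 - p0
    t = np.clip(((rr - p0[0]) * v[0] + (cc - p0[1]) * v[1]) / (v @ v), 0.0, 1.0)
    return np.hypot(rr - (p0[0] + t * v[0]), cc - (p0[1] + t * v[1]))


def truth_ring_mean(true_map: np.ndarray, geometry: FundusGeometry) -> float:
    """Generator-side ring mean (6 <= ecc < 8 degrees) of a truth map."""
    H, W = true_map.shape
    fr, fc = geometry.fovea_center_px
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    ecc = np.hypot(rr - fr, cc - fc) * geometry.degrees_per_px
    return float(true_map[(ecc >= 6.0) & (ecc < 8.0)].mean())


def render_qaf_frames(true_qaf_map: np.ndarray, lens: LensProfile,
                      geometry: FundusGeometry, rng: np.random.Generator,
                      cfg: GeneratorConfig | None = None,
                      n_frames: int = 12):
    """Render the 12-frame QAF series.

    Per pixel: ``GV = zero_gv + k_inst * true_qaf * T(488) * T(em)`` (+ an
    optional additive lens-fluorescence term, off by default), with small
    random integer per-frame translations of the fundus content; the internal
    reference strip is stamped at fixed pixels with lens-independent level.
    Returns ``(frames, shifts)`` with the applied (drow, dcol) jitter log.
    """
    cfg = cfg or GeneratorConfig()
    H, W = geometry.image_size_px
    if true_qaf_map.shape != (H, W):
        raise ValueError("true_qaf_map does not match geometry.image_size_px")
    T = total_transmission(lens, cfg)
    fundus = geometry.zero_gv + cfg.qaf_k_inst * (
        true_qaf_map * T
        + cfg.lens_fundus_fluorescence_weight * lens.fluorophore_level)
    m = cfg.jitter_max_px
    padded = np.pad(fundus, m, mode="reflect")
    r0, r1, c0, c1 = geometry.reference_region
    frames = np.empty((n_frames, H, W), dtype=float)
    shifts = []
    for f in range(n_frames):
        if cfg.noise_scale > 0 and f > 0:
            # the first frame anchors the coordinate system; later frames are
            # cropped at offset (dy, dx), i.e. their content appears shifted by
            # (-dy, -dx) relative to frame 1
            dy, dx = int(rng.integers(-m, m + 1)), int(rng.integers(-m, m + 1))
        else:
            dy, dx = 0, 0
        shifts.append((dy, dx))
        frame = padded[m + dy:m + dy + H, m + dx:m + dx + W].copy()
        frame[r0:r1, c0:c1] = geometry.zero_gv + cfg.qaf_k_inst * cfg.qaf_ref_level
        frames[f] = _poisson_noise(frame, cfg.ppg_qaf, rng, cfg.noise_scale)
    return frames, shifts


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _draw_age(rng: np.random.Generator, cfg: GeneratorConfig) -> float:
    from scipy.stats import truncnorm
    a = (cfg.age_min - cfg.age_parent_mean) / cfg.age_parent_sd
    b = (cfg.age_max - cfg.age_parent_mean) / cfg.age_parent_sd
    return float(truncnorm.rvs(a, b, loc=cfg.age_parent_mean,
                               scale=cfg.age_parent_sd, random_state=rng))


def generate_subject(subject_id: str, seed: int,
                     cfg: GeneratorConfig,
                     scheimpflug_shape: tuple = (96, 96)) -> SubjectRecord:
    """Draw all per-subject ground truth (age, latents, lens, true QAF level,
    score targets) from the subject's own random substream."""
    rng = subject_rng(seed, subject_id, "truth")
    age = _draw_age(rng, cfg)
    A = float(rng.standard_normal()) if cfg.noise_scale > 0 else 0.0
    rho = cfg.od_latent_loading
    z = float(rng.standard_normal()) if cfg.noise_scale > 0 else 0.0
    u = rho * A + np.sqrt(max(0.0, 1 - rho ** 2)) * z
    mean_curve = cfg.od_scale * _softplus(cfg.od_slope * (age - cfg.od_onset))
    s = cfg.od_sigma * cfg.noise_scale
    d = float(mean_curve * np.exp(s * u - s ** 2 / 2.0))
    lqaf_t = _lqaf_target(age, A, rng, cfg)
    acoct_t = _acoct_target(d, rng, cfg)
    axial = float(np.clip(cfg.lens_axial_mean_mm + cfg.lens_axial_sd_mm
                          * (rng.standard_normal() if cfg.noise_scale > 0 else 0.0),
                          1.0, 7.0))
    pattern = PATTERNS[int(rng.choice(len(PATTERNS),
                                      p=np.asarray(cfg.pattern_probs)
                                      / np.sum(cfg.pattern_probs)))]
    lens = LensProfile(d, _fluorophore_from_target(lqaf_t, d, cfg), pattern, axial)
    age_std = (age - cfg.age_center) / cfg.age_scale
    level = (cfg.qaf_mean + cfg.qaf_age_slope * (age - cfg.age_center)
             + cfg.qaf_latent_sd * A
             + cfg.qaf_noise_sd * (float(rng.standard_normal())
                                   if cfg.noise_scale > 0 else 0.0))
    level = float(max(level, cfg.qaf_floor))
    return SubjectRecord(subject_id=subject_id, age=age, phakic=True, lens=lens,
                         qaf8_true=level, lqaf_target=lqaf_t, acoct_target=acoct_t,
                         latent_aging=A, od_latent=u)


def tabular_scores(rec: SubjectRecord, seed: int, cfg: GeneratorConfig,
                   scheimpflug_shape: tuple = (96, 96)) -> dict:
    """Analytic measurement model: the noise-free measurement equations of the
    rendered pipeline plus the subject-level noise already in the score
    targets (rendering adds only small shot noise on top of these)."""
    mean0, sd0, max0 = scheimpflug_nucleus_stats(rec.lens.pattern,
                                                 scheimpflug_shape, cfg)
    pns_mean = mean0 * rec.lens.optical_density_488
    return {
        "lqaf": rec.lqaf_target,
        "acoct_reflectivity": rec.acoct_target,
        "pns_mean_density": pns_mean,
        "pns_sd_density": sd0 * rec.lens.optical_density_488,
        "pns_max_density": max0 * rec.lens.optical_density_488,
        "pns_grade": pns_grade_from_mean(pns_mean, cfg),
    }


def generate_cohort(n: int, surgery_n: int, seed: int,
                    cfg: GeneratorConfig | None = None,
                    scheimpflug_shape: tuple = (96, 96)) -> list:
    """Generate ``n`` subjects; a surgery subset of size ``surgery_n`` (biased
    toward higher lens opacity) carries post-surgery QAF.  Scores are filled
    with the analytic measurement model; the rendered pipeline overwrites them
    with image-derived values."""
    if surgery_n > n:
        raise ValueError("surgery_n cannot exceed n")
    records = [generate_subject(f"S{i:04d}", seed, cfg or GeneratorConfig(),
                                scheimpflug_shape)
               for i in range(1, n + 1)]
    cfg = cfg or GeneratorConfig()
    root = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence([seed, zlib.crc32(b"cohort")])))
    u = np.array([r.od_latent if r.od_latent is not None else 0.0 for r in records])
    w = np.exp(cfg.surgery_bias * (u - u.mean()) / (u.std() + 1e-12))
    idx = root.choice(n, size=surgery_n, replace=False, p=w / w.sum()) \
        if surgery_n > 0 else np.array([], dtype=int)
    surgery = set(int(i) for i in idx)
    for i, rec in enumerate(records):
        rec.scores = tabular_scores(rec, seed, cfg, scheimpflug_shape)
        mrng = subject_rng(seed, rec.subject_id, "measure")
        T = total_transmission(rec.lens, cfg)
        noise = cfg.qaf8_meas_sd * cfg.noise_scale
        rec.qaf8_pre = float(rec.qaf8_true * T + noise * mrng.standard_normal())
        if i in surgery:
            rec.qaf8_post = float(rec.qaf8_true + noise * mrng.standard_normal())
    return records


def cohort_frame(records: list) -> pd.DataFrame:
    """Analysis-facing cohort table (one row per eye; no ground truth columns)."""
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id, "age": r.age, "phakic": r.phakic,
            "lqaf": r.scores.get("lqaf"),
            "acoct_reflectivity": r.scores.get("acoct_reflectivity"),
            "pns_grade": r.scores.get("pns_grade"),
            "pns_mean_density": r.scores.get("pns_mean_density"),
            "pns_sd_density": r.scores.get("pns_sd_density"),
            "pns_max_density": r.scores.get("pns_max_density"),
            "qaf8_pre": r.qaf8_pre, "qaf8_post": r.qaf8_post,
        })
    return pd.DataFrame(rows)


def truth_frame(records: list) -> pd.DataFrame:
    """Generator-only ground truth, kept separate from analysis inputs."""
    return pd.DataFrame([{
        "subject_id": r.subject_id, "qaf8_true": r.qaf8_true,
        "optical_density_488": r.lens.optical_density_488,
        "fluorophore_level": r.lens.fluorophore_level,
        "pattern": r.lens.pattern, "latent_aging": r.latent_aging,
    } for r in records])
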