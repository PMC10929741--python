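"""Configuration objects for the synthetic study and the analysis pipeline.

All tunable constants of the eye/instrument simulator and of the statistical
models live here as frozen-by-default dataclasses, so that a study run is a
pure function of ``(config, seed)``.  Calibrated constants (squash-interval
offsets, PNS grade edges, the age-based correction line, the surgery-subset
opacity bias) were fixed once with ``scripts/calibrate_generator.py`` against
the cohort summary statistics the generator is meant to emulate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import yaml

EXCITATION_NM = 488.0  # QAF excitation wavelength


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-eye generator.

    The generator draws, per subject, an age, a systemic-aging latent factor
    ``A`` (shared between lens fluorophore accumulation, lens optical density
    and retinal autofluorescence level), a lens profile, and a ground-truth
    retinal QAF level; images are rendered from these with Poisson-like noise.
    """

    # --- ages: truncated normal, parent parameters solved so that the
    # post-truncation mean equals 63 years (target cohort: 63 +/- 17 [21-87])
    age_parent_mean: float = 68.1411
    age_parent_sd: float = 19.0
    age_min: float = 21.0
    age_max: float = 87.0
    age_center: float = 63.0   # centering constant for standardized age
    age_scale: float = 14.4898   # empirical SD of the truncated age distribution

    # --- lens optical density at 488 nm:
    # d = od_scale * softplus(od_slope*(age - od_onset)) * exp(s*u - s^2/2)
    # with u = od_latent_loading*A + sqrt(1-rho^2)*z  (lognormal individual noise)
    od_slope: float = 0.09
    od_onset: float = 62.0
    od_scale: float = 0.22
    od_sigma: float = 0.5
    od_latent_loading: float = 0.5

    # --- ground-truth retinal QAF level (a.u., QAF8-ring scale)
    qaf_mean: float = 148.6
    qaf_age_slope: float = 1.38      # a.u. per year
    qaf_latent_sd: float = 20.0      # shared systemic-aging component
    qaf_noise_sd: float = 28.0       # idiosyncratic component
    qaf_floor: float = 30.0

    # --- lens fluorophore / LQAF score target, squashed into an open interval
    # target = lo + (hi-lo) * sigmoid(mu + s*(w_age*age_std + w_A*A + w_e*eps))
    lqaf_lo: float = 3.0
    lqaf_hi: float = 27.0
    lqaf_mu: float = 0.2089           # calibrated: rendered-score mean ~15.90
    lqaf_latent_scale: float = 1.5991
    lqaf_w_age: float = 0.45
    lqaf_w_latent: float = 0.80
    lqaf_w_noise: float = 0.35
    lqaf_scatter_weight: float = 1.0  # a.u. of LQAF score per unit optical density

    # --- AC-OCT relative-reflectivity target (monotone in d, noisy)
    acoct_lo: float = 2.3
    acoct_hi: float = 6.6
    acoct_gain: float = 1.1          # on log10(d + d0)
    acoct_log_offset: float = 0.02
    acoct_center: float = -0.5873      # calibrated: score mean ~4.26
    acoct_noise_sd: float = 1.1702     # subject-level measurement noise (latent scale)

    # --- Scheimpflug densitometry / PNS
    pns_gain: float = 60.0           # nucleus density a.u. per unit optical density
    pattern_probs: tuple = (0.60, 0.25, 0.15)  # nuclear, cortical, posterior_subcapsular
    pattern_factors: tuple = (1.0, 0.45, 0.70)
    # grade edges: calibrated quantiles of the nucleus mean-density distribution
    pns_grade_edges: tuple = (0.0394, 2.8014, 9.5385, 16.612, 19.3631)

    # --- axial geometry of the LQAF acquisition (64 slabs over 8 mm)
    lqaf_n_slabs: int = 64
    lqaf_depth_mm: float = 8.0
    lens_axial_mean_mm: float = 4.2
    lens_axial_sd_mm: float = 0.4
    lqaf_axial_sigma_mm: float = 0.9

    # --- rendering constants
    lqaf_bg_gv: float = 2.0
    lqaf_gain_gv: float = 25.0       # gray value per a.u. of fluorophore signal
    lqaf_ref_gv: float = 100.0
    lqaf_score_scale: float = 4.0    # lqaf = scale * max center mean / ref mean
    acoct_cornea_gv: float = 200.0
    acoct_score_scale: float = 10.0
    qaf_k_inst: float = 100.0        # gray value per a.u. of QAF
    qaf_ref_level: float = 100.0     # internal-reference level, a.u.
    zero_gv: float = 0.0
    emission_nm: float = 560.0       # effective emission wavelength
    jitter_max_px: int = 3
    # Poisson noise: counts = Poisson(gv * ppg / noise_scale^2) * noise_scale^2 / ppg
    ppg_qaf: float = 0.2
    ppg_lqaf: float = 4.0
    ppg_acoct: float = 2.0
    ppg_scheimpflug: float = 2.0
    noise_scale: float = 1.0         # 0 disables all stochastic rendering noise
    attenuation_enabled: bool = True
    lens_fundus_fluorescence_weight: float = 0.0  # additive lens AF on the fundus image

    # tabular-mode measurement noise for the QAF8 ring (a.u.)
    qaf8_meas_sd: float = 1.5

    # --- surgery-subset selection: weights softmax(bias * standardized log-density)
    surgery_bias: float = 1.2023

    def null(self) -> "GeneratorConfig":
        """No-association configuration: attenuation off and all shared-latent
        loadings severed, so lens scores carry no information about retinal QAF."""
        return dataclasses.replace(
            self,
            attenuation_enabled=False,
            od_latent_loading=0.0,
            qaf_latent_sd=0.0,
            lqaf_w_latent=0.0,
            lqaf_w_noise=0.916,  # keep the LQAF latent at unit total scale
        )


@dataclass
class AgeCorrectionConfig:
    """Log-linear age-based lens correction factor CF(age) >= 1 (phakic eyes only).

    ``CF(age) = max(1, 10**(c0 + c1*(age - age_ref)))`` — a placeholder with the
    qualitative shape of the classical age-based media correction, calibrated to
    the generator's mean total optical density (excitation + emission path).
    """

    c0: float = 0.3206
    c1: float = 0.01452     # per year
    age_ref: float = 63.0
    age_domain: tuple = (18.0, 100.0)


@dataclass
class SplineConfig:
    """Varying-coefficient spline model settings."""

    n_basis: int = 8
    degree: int = 3
    gcv_grid_size: int = 30
    gcv_log10_min: float = -6.0
    gcv_log10_max: float = 8.0
    gcv_passes: int = 2
    # effective-df inflation in the GCV score; values above 1 counteract the
    # occasional undersmoothing of plain GCV and keep the approximate
    # smooth-term tests near their nominal size
    gcv_gamma: float = 2.0
    selector: str = "gcv"   # "gcv" or "reml"


@dataclass
class StudyConfig:
    """Full end-to-end study: cohort size, image geometry, model settings."""

    n: int = 130
    surgery_n: int = 30
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    agecorrection: AgeCorrectionConfig = field(default_factory=AgeCorrectionConfig)
    spline: SplineConfig = field(default_factory=SplineConfig)

    # image geometry of the synthetic acquisitions (instrument native: 768 px /
    # 30 degrees; the default study renders at reduced size for desk-scale runs)
    qaf_size_px: int = 160
    field_degrees: float = 30.0
    lqaf_rows: int = 64
    lqaf_cols: int = 64
    acoct_shape: tuple = (96, 128)
    scheimpflug_shape: tuple = (96, 96)
    n_qaf_frames: int = 12

    lasso_response: str = "post"    # "post" (post-surgery QAF) or "diff" (pre - post)
    snr_threshold: float = 3.0      # reference-region SNR below which an eye is excluded
    render: bool = True             # False: analytic (tabular) measurement model

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["generator"] = GeneratorConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.get("generator", {}).items()})
        raw["agecorrection"] = AgeCorrectionConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.get("agecorrection", {}).items()})
        raw["spline"] = SplineConfig(**raw.get("spline", {}))
        for k in ("acoct_shape", "scheimpflug_shape"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)
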