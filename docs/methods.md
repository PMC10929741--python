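# Methods

## Optical model

The simulator treats the eye as a two-pass attenuator around a fluorescent
retina. A lens with base-10 optical density `d` at 488 nm transmits

```
T(λ) = 10^(−d · (488/λ)⁴)
```

— the λ⁻⁴ factor models Rayleigh scattering by lens opacities, which makes
the blue excitation line far more vulnerable than the emission band. The
fundus gray value of a QAF frame is

```
GV = zero_gv + k_inst · QAF_true · T(488) · T(λ_em)
```

with a single effective emission wavelength `λ_em = 560 nm` (mid emission
band) instead of an integral over 500–750 nm; the integral version would only
change the effective round-trip exponent by a few percent and is noted as an
extension. The instrument-internal reference strip is stamped into each frame
at fixed pixels with a lens-independent level: it is excited and captured
inside the device, so the subject's optics never touch it. This asymmetry —
fundus attenuated, reference not — is the entire mechanism by which cataract
depresses normalized QAF, and it is what the correction models undo.

An optional additive lens-fluorescence term on the fundus image exists but
defaults to 0: opacification dominates the intrinsic lens signal in the
fundus-focused acquisition, while the lens-focused LQAF stack captures that
intrinsic fluorescence directly.

## Subject model

Per subject the generator draws:

- **age** — truncated normal on [21, 87]; parent parameters were solved
  numerically so the post-truncation mean is 63.0 years (parent mean 68.14,
  SD 19; post-truncation SD 14.49). The joint target "mean 63, SD 17, range
  21–87" is not exactly attainable for a truncated normal; the mean was
  prioritized.
- **a systemic-aging factor `A ~ N(0,1)`** shared between lens fluorophore
  accumulation, lens optical density, and retinal autofluorescence level.
  This is the generator's stand-in for the common biological drivers
  (oxidative stress, glycation) that make lens fluorescence informative about
  retinal autofluorescence beyond age alone; without some shared factor, lens
  scores could not predict post-surgery QAF conditional on age at all.
- **optical density** `d = 0.22 · softplus(0.09 · (age − 62)) ·
  exp(0.5u − 0.125)`, `u = 0.5A + √0.75·z` — a softplus mean curve (near
  zero in youth, ~linear after onset) with multiplicative lognormal
  individual noise. Mean total round-trip attenuation at 63 years is ≈ 2×
  (CF ≈ 2), reaching ≈ 5–6× for severe cataract.
- **true retinal QAF level** (QAF8-ring scale): `148.6 + 1.38·(age−63) +
  20·A + 28·ε`, floored at 30 a.u. — mean anchored near the observed
  cohort-level intercept, rising with age, with roughly a quarter of the
  variance from age, a quarter from the shared factor, and half idiosyncratic.
- **score targets** — the LQAF and AC-OCT score distributions are logistic
  squashes of latent Gaussians into open intervals slightly inside the
  printed cohort spans ([3, 27] and [2.3, 6.6] a.u.), so finite samples stay
  inside the published ranges. Squash location/scale parameters were solved
  by Monte-Carlo so the rendered scores reproduce the cohort means and SDs
  (LQAF 15.90 ± 6.65, AC-OCT 4.26 ± 1.03 a.u.); see
  `scripts/calibrate_generator.py`. The AC-OCT latent is mostly measurement
  noise (making it the weakest opacity proxy); PNS measures `d` through the
  rendered density map (second-weakest link to retinal QAF); LQAF loads
  directly on `A` (strongest). A clear (pseudophakic) lens has zero density,
  zero fluorophore, and sits at the AC-OCT reflectivity floor — the printed
  lower bound of the score range is positive, so a clear lens does not map
  to zero.
- **cataract pattern** — nuclear (60%), cortical (25%), posterior
  subcapsular (15%); patterns shape the Scheimpflug density map (central
  blob / peripheral spokes / thin posterior layer). Because PNS is a nucleus
  score, cortical and posterior-subcapsular opacities contribute little to
  the nucleus mean — a deliberate realism that adds noise to the PNS→opacity
  link. Grade edges are frozen quantiles of the nucleus-mean distribution
  chosen to reproduce the cohort grade frequencies (17/40/26/11/2/4%).
- **surgery subset** — drawn without replacement with weights
  `exp(1.2 · standardized log-density latent)`, calibrated so the subset's
  mean PNS grade is ≈ 2 (mean LQAF ≈ 19 a.u.), emulating a cataract-clinic
  referral population.

Randomness is organized as one root seed with per-subject substreams keyed by
a stable hash of the subject id, so cohorts are reproducible bit-for-bit and
insensitive to generation order.

## Acquisition rendering

All modalities add Poisson shot noise (gray values converted to photon counts
at a configurable gain; `noise_scale = 0` disables all stochastic effects
including eye-movement jitter). Default rendered sizes are reduced relative
to the instrument's native 768 × 768 / 30° frame (QAF 160 px, LQAF
64 × 64 × 64, AC-OCT 96 × 128, Scheimpflug 96 × 96) to keep a full 130-eye
study around ten seconds; all measuring regions scale with the geometry, and
the native geometry (60 × 60-pixel LQAF center, 200 × 18-pixel reference
strip at 768 px) remains the per-operation default. The 12 QAF frames jitter
by integer translations of up to ±3 px relative to the first frame, which
anchors the coordinate system.

## Measurement pipeline

- **LQAF** — highest center-region mean over the 64 slabs divided by the
  internal-reference mean; the reference denominator comes from the same slab
  that maximizes the center mean (a per-slab-ratio alternative and a
  dark-offset subtraction are available as flags, both off by default since
  the source protocol does not specify them).
- **AC-OCT reflectivity** — min–max normalization of the section to [0, 1],
  then lens-ROI mean over cornea-ROI mean, scaled onto the reported a.u.
  range. ROIs are supplied per image (the generator emits them); no
  segmentation is attempted.
- **PNS** — mean/SD/max over the nucleus mask; grade = number of calibrated
  edges ≤ mean, inclusive on the left (a mean exactly at edge k grades k).
  The manufacturer's formula is unpublished; this reconstruction is
  calibrated, not reverse-engineered.
- **QAF8** — frames are aligned to frame 1 by the integer translation
  maximizing Pearson correlation over a fixed interior window (the static
  reference strip is excluded from the window: registration follows retinal
  content, and alignment would smear the strip). Averaging is overlap-only at
  borders. The reference mean for normalization is taken from the raw frames
  for the same reason. Normalization is
  `QAF = scale_k (GV − zero_gv)/(GV_ref − zero_gv)` with `scale_k` equal to
  the generator's reference level, making the clear-lens noise-free pipeline
  an exact identity (verified to 1e-6). The ring covers 6° ≤ eccentricity
  < 8° (half-open, avoiding double counting with adjacent annuli), measured
  isotropically in the image plane with no axial-length correction; eight 45°
  segments run counter-clockwise from the image-x axis; the ring mean is the
  mean over all ring pixels (pixel-weighted, not the unweighted mean of the
  eight segment means — a flag-free documented choice since the two differ
  only through rounding of segment boundaries). No vessel-pixel exclusion is
  applied by default; a mask hook exists.

## Statistical models

- **Standardization**: mean 0, SD 1 with the n−1 denominator.
- **LASSO**: objective `(1/2n)‖y − b₀ − Zβ‖² + λ‖β‖₁`, cyclic coordinate
  descent with warm starts along a 100-point log-spaced path from
  `λ_max = max_j |Z_jᵀ(y−ȳ)|/n` (all slopes exactly zero) down to
  `λ_max·10⁻⁶`; convergence when the largest coefficient change in a sweep is
  below 1e-9. The lower path end is a proxy for ordinary least squares; the
  1e-6 ratio keeps the soft-threshold bias (≈ λ_min) well below the 1e-4
  agreement tolerance asserted against the closed-form OLS solution. λ is
  chosen by minimum leave-one-out MSE (n exact refits per λ); the one-SE rule
  is not used. KKT subgradient conditions are asserted along the whole path
  in the tests, and scikit-learn's LASSO serves as an independent
  cross-check, never as the implementation.
- **Backward selection**: criterion is the exact hat-matrix LOO-MSE of OLS;
  at each step the variable whose removal most improves it is dropped,
  stopping when no removal improves; exact ties break toward the smaller
  absolute standardized coefficient.
- **Age-based factor**: `CF(age) = max(1, 10^(0.3206 + 0.01452(age − 63)))`,
  a log-linear placeholder fit to the generator's mean round-trip optical
  density (the published age-based formula's exact coefficients are not
  reproduced here); applied to phakic eyes only. The spec of the factor is
  pluggable (log-linear or lookup table).
- **Varying-coefficient spline model**: design
  `[1 | B(age)Z₁ | LQAF⊙B(age) | PNS⊙B(age)]` with a cubic B-spline basis of
  dimension 8 (interior knots at age quantiles), a sum-to-zero constraint on
  f₁ (absorbed via a null-space reparameterization, making the intercept the
  mean response at average age for zero scores), and per-term
  second-derivative penalties `∫f″² ` computed exactly by Gauss–Legendre
  quadrature. Fitting solves an augmented least-squares system (numerically
  stable into the penalty → ∞ limit, where the model collapses to OLS on
  `[1, age, LQAF, LQAF·age, PNS, PNS·age]` — an identity the tests assert).
  Smoothing parameters are selected coordinate-wise on a fixed 30-point log
  grid by GCV with an effective-df inflation factor γ = 2.0; plain GCV
  (γ = 1) undersmooths under the null and inflates the smooth-term test size
  to ≈ 8%, while γ = 2 restores ≈ 5–6% (the Wald construction itself is
  exact at fixed λ, verified against a closed-form F-test). A REML selector
  is available via `SplineConfig.selector = "reml"`. Effective degrees of
  freedom are traces of the term blocks of `(XᵀX+S)⁻¹XᵀX`; term tests are
  Wald-type on the Bayesian coefficient covariance truncated at rank
  `round(edf)`, referred to `F(r, n − edf_total)` — approximate by
  construction, with calibration verified by simulation rather than claimed
  exactly. `R²` is adjusted; deviance explained is `1 − RSS/TSS`. No random
  effects are included: the design has one observation per eye and no
  grouping factor, so the "mixed" extension would be unidentified.
- **Evaluation**: the spline model is trained on the full cohort with
  post-surgery QAF as the response for surgery eyes and ground-truth QAF for
  the rest — a generator privilege the clinical study lacked, stated here
  prominently; all reported errors are computed on the surgery subset only,
  against measured post-surgery QAF. Both in-sample and leave-one-out
  cross-validated spline MAEs are reported and labelled. Image-quality
  exclusion drops eyes whose reference-strip SNR falls below a threshold
  (default 3); under default noise this rarely triggers — the synthetic noise
  model has no catastrophic-failure mode, unlike clinical acquisition.

## What the generator does and does not emulate

It reproduces the photometric chain (reference normalization, double-pass
attenuation, shot noise, jitter), the correlation structure among age, lens
scores and retinal QAF, the cohort score distributions, and the
surgery-subset opacity bias. It does not attempt anatomical realism (the
truth maps are smooth radial fields with a dark disc ellipse and a few vessel
strokes — only ring statistics are consumed), photopigment-bleaching
kinetics, refraction/magnification effects, vessel-bifurcation multimodal
registration (translation-only alignment replaces it), or clinically
realistic failure modes behind image-quality exclusions. Passing tests
therefore validate the analysis logic and its statistical behavior under the
stated optical model, not clinical performance.

## Known limitations

- Smooth-term p-values are approximate; their size was verified at ≈ 5–6% by
  simulation under the no-association configuration, but selection-then-test
  effects are only mitigated (γ-inflated GCV), not removed.
- The backward-elimination *order* between the two weakest predictors is
  intrinsically noisy at n = 30: the expected order (AC-OCT out first, PNS
  second) is the modal outcome but occurs in only ≈ 30% of seeds, because an
  order that is both confident (large PNS t-statistic) and followed by PNS's
  own elimination (small PNS t-statistic) cannot hold simultaneously.
- The age-based correction factor is a calibrated monotone placeholder, not
  the published formula.
- A single effective emission wavelength approximates the emission-band
  integral.
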