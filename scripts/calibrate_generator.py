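"""One-off calibration of the synthetic-generator constants.

Solves the generator's free calibration constants against the cohort summary
statistics it is meant to emulate (score means/SDs, age distribution, PNS
grade frequencies, surgery-subset opacity bias, and the mean optical density
behind the age-based correction line), and prints the values that are frozen
into ``qaflens.config``.  Run from the repository root:

    python scripts/calibrate_generator.py
"""

import numpy as np
from scipy import optimize
from scipy.stats import truncnorm

from qaflens.config import GeneratorConfig
from qaflens import synthetic as syn

TARGETS = {"age_mean": 63.0, "lqaf_mean": 15.90, "lqaf_sd": 6.65,
           "acoct_mean": 4.26, "acoct_sd": 1.03,
           "pns_cum": (0.17, 0.57, 0.83, 0.94, 0.96),
           "surgery_pns_grade": 2.0}

cfg = GeneratorConfig()
rng = np.random.default_rng(20240311)
N = 400_000

# --- 1. age distribution: parent mean such that the truncated mean is 63
def trunc_mean(mu):
    a = (cfg.age_min - mu) / cfg.age_parent_sd
    b = (cfg.age_max - mu) / cfg.age_parent_sd
    return truncnorm.mean(a, b, loc=mu, scale=cfg.age_parent_sd)

mu_age = optimize.brentq(lambda m: trunc_mean(m) - TARGETS["age_mean"], 55, 85)
a = (cfg.age_min - mu_age) / cfg.age_parent_sd
b = (cfg.age_max - mu_age) / cfg.age_parent_sd
sd_trunc = truncnorm.std(a, b, loc=mu_age, scale=cfg.age_parent_sd)
print(f"age_parent_mean = {mu_age:.4f}   (truncated SD = {sd_trunc:.4f})")

ages = truncnorm.rvs(a, b, loc=mu_age, scale=cfg.age_parent_sd,
                     size=N, random_state=rng)
age_std = (ages - TARGETS["age_mean"]) / sd_trunc

# --- 2. optical density draws (shared systemic latent A)
A = rng.standard_normal(N)
z = rng.standard_normal(N)
rho = cfg.od_latent_loading
u = rho * A + np.sqrt(1 - rho ** 2) * z
mean_curve = cfg.od_scale * np.logaddexp(0, cfg.od_slope * (ages - cfg.od_onset))
d = mean_curve * np.exp(cfg.od_sigma * u - cfg.od_sigma ** 2 / 2)

# --- 3. LQAF squash: solve (mu, scale) for mean 15.90 / SD 6.65 of the
# rendered score (= target, with the fluorophore floor at zero applied)
eps = rng.standard_normal(N)
offset = cfg.lqaf_score_scale * cfg.lqaf_bg_gv / cfg.lqaf_ref_gv

def lqaf_measured(p):
    mu, s = p
    lat = mu + s * (cfg.lqaf_w_age * age_std + cfg.lqaf_w_latent * A
                    + cfg.lqaf_w_noise * eps)
    target = cfg.lqaf_lo + (cfg.lqaf_hi - cfg.lqaf_lo) / (1 + np.exp(-lat))
    return np.maximum(target, offset + cfg.lqaf_scatter_weight * d)

sol = optimize.fsolve(lambda p: [lqaf_measured(p).mean() - TARGETS["lqaf_mean"],
                                 lqaf_measured(p).std() - TARGETS["lqaf_sd"]],
                      x0=[0.15, 1.1], full_output=False)
lqaf_mu, lqaf_scale = sol
m = lqaf_measured(sol)
print(f"lqaf_mu = {lqaf_mu:.4f}, lqaf_latent_scale = {lqaf_scale:.4f}"
      f"   (mean {m.mean():.3f}, sd {m.std():.3f},"
      f" range [{m.min():.2f}, {m.max():.2f}])")

# --- 4. AC-OCT squash: solve (center, noise_sd) for mean 4.26 / SD 1.03
eps2 = rng.standard_normal(N)

def acoct_measured(p):
    center, nsd = p
    lat = cfg.acoct_gain * (np.log10(d + cfg.acoct_log_offset) - center) \
        + nsd * eps2
    return cfg.acoct_lo + (cfg.acoct_hi - cfg.acoct_lo) / (1 + np.exp(-lat))

sol2 = optimize.fsolve(lambda p: [acoct_measured(p).mean() - TARGETS["acoct_mean"],
                                  acoct_measured(p).std() - TARGETS["acoct_sd"]],
                       x0=[-0.75, 0.85])
ac_center, ac_noise = sol2
m2 = acoct_measured(sol2)
print(f"acoct_center = {ac_center:.4f}, acoct_noise_sd = {ac_noise:.4f}"
      f"   (mean {m2.mean():.3f}, sd {m2.std():.3f},"
      f" range [{m2.min():.2f}, {m2.max():.2f}])")

# --- 5. PNS grade edges: quantiles of nucleus mean density matching the
# target cumulative grade frequencies
patterns = rng.choice(3, size=N, p=np.array(cfg.pattern_probs)
                      / sum(cfg.pattern_probs))
mean0 = np.array([syn.scheimpflug_nucleus_stats(p, (96, 96), cfg)[0]
                  for p in syn.PATTERNS])
pns_mean = mean0[patterns] * d
edges = np.quantile(pns_mean, TARGETS["pns_cum"])
print("pns_grade_edges =", tuple(round(float(e), 4) for e in edges))
grades = (pns_mean[:, None] >= edges[None]).sum(axis=1)
print("   grade freqs:", np.bincount(grades, minlength=6) / N,
      " grade mean:", grades.mean().round(3))

# --- 6. age-based correction line: log-linear fit of total optical density
# (excitation + emission path) on age
od_total = d * (1.0 + (488.0 / cfg.emission_nm) ** 4 / (560.0 / 560.0))
od_total = d * (1.0 + (488.0 / cfg.emission_nm) ** 4)
X = np.column_stack([np.ones(N), ages - 63.0])
beta, *_ = np.linalg.lstsq(X, od_total, rcond=None)
print(f"agecorrection: c0 = {beta[0]:.4f}, c1 = {beta[1]:.5f} (per year, at 63)")

# --- 7. surgery-subset bias: weights exp(bias * standardized od latent);
# importance-weighted grade mean should hit the cataract-subgroup target
u_std = (u - u.mean()) / u.std()
def weighted_grade(bias):
    w = np.exp(bias * u_std)
    return (w * grades).sum() / w.sum()

bias = optimize.brentq(lambda b: weighted_grade(b) - TARGETS["surgery_pns_grade"],
                       0.1, 6.0)
w = np.exp(bias * u_std)
print(f"surgery_bias = {bias:.4f}   (weighted LQAF {np.average(m, weights=w):.2f},"
      f" weighted acoct {np.average(m2, weights=w):.2f})")
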