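"""End-to-end study replica and comparison metrics.

``run_study`` composes the whole analysis on synthetic data: generate a
cohort, render the acquisitions, extract the three lens scores and the QAF8
ring values, fit the LASSO / backward-selection / varying-coefficient spline
models on the cataract-surgery subset, and compare the spline-based
personalized correction against the classical age-based correction factor by
mean absolute error against the post-surgery (clear lens) QAF.

A deliberate generator privilege: the spline model is trained on the full
cohort using ground-truth QAF as the response for eyes without surgery (the
clinical study only had post-surgery QAF for the surgery subset).  All
headline metrics are evaluated on the surgery subset only, where measured
post-surgery QAF exists.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import StudyConfig
from . import synthetic as syn
from . import lens_scores as ls
from . import qaf_retina as qr
from . import models


LASSO_PREDICTORS = ["age", "lqaf", "pns_grade", "acoct_reflectivity"]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_mae(pred, truth):
    """Mean absolute error and the sample SD (n-1) of the absolute errors.

    A single pair has no SD; it is reported as 0.0 (with a warning)."""
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth have different lengths")
    if pred.size == 0:
        raise ValueError("need at least one pair")
    err = np.abs(pred - truth)
    if err.size == 1:
        warnings.warn("single pair: SD of absolute errors is undefined, reporting 0")
        return float(err[0]), 0.0
    return float(err.mean()), float(err.std(ddof=1))


def linear_r2(x, y) -> float:
    """R^2 of the simple linear regression of y on x (squared Pearson r)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y")
    r = np.corrcoef(x, y)[0, 1]
    return float(r ** 2)


# ---------------------------------------------------------------------------
# rendered measurement of one subject
# ---------------------------------------------------------------------------

def render_subject_images(rec: syn.SubjectRecord, seed: int, cfg: StudyConfig):
    """Render all acquisitions for one subject (pre-surgery visit; plus a
    post-surgery QAF series for the surgery subset).  Returns a dict of
    arrays and sidecar metadata."""
    gen = cfg.generator
    rng = syn.subject_rng(seed, rec.subject_id, "render")
    geometry = syn.FundusGeometry.default(cfg.qaf_size_px, cfg.field_degrees,
                                          gen.zero_gv)
    stack = syn.render_lqaf_stack(rec.lens, rng, gen, cfg.lqaf_rows, cfg.lqaf_cols)
    acoct, rois = syn.render_acoct_section(rec.lens, rng, gen, cfg.acoct_shape,
                                           target=rec.acoct_target)
    dmap, mask = syn.render_scheimpflug_densitometry(rec.lens, rng, gen,
                                                     cfg.scheimpflug_shape)
    truth_map = syn.generate_truth_map(rec.qaf8_true, geometry, rng, gen)
    frames, shifts = syn.render_qaf_frames(truth_map, rec.lens, geometry, rng,
                                           gen, cfg.n_qaf_frames)
    out = {"geometry": geometry, "lqaf_stack": stack, "acoct": acoct,
           "acoct_rois": rois, "scheimpflug": dmap, "nucleus_mask": mask,
           "qaf_frames": frames, "jitter": shifts, "truth_map": truth_map}
    if rec.qaf8_post is not None:
        rng_post = syn.subject_rng(seed, rec.subject_id, "render-post")
        frames_post, _ = syn.render_qaf_frames(truth_map, syn.LensProfile.clear(),
                                               geometry, rng_post, gen,
                                               cfg.n_qaf_frames)
        out["qaf_frames_post"] = frames_post
    return out


def reference_snr(frames: np.ndarray, geometry: syn.FundusGeometry) -> float:
    """Image-quality metric: mean over SD of the internal-reference pixels
    across the raw frames."""
    r0, r1, c0, c1 = geometry.reference_region
    strip = np.asarray(frames, float)[:, r0:r1, c0:c1]
    sd = strip.std()
    return float(strip.mean() / sd) if sd > 0 else np.inf


def score_subject(rec: syn.SubjectRecord, images: dict, cfg: StudyConfig) -> dict:
    """Extract all image-derived measurements for one subject."""
    gen = cfg.generator
    geometry = images["geometry"]
    lgeo = syn.lqaf_geometry(cfg.lqaf_rows, cfg.lqaf_cols)
    lqaf = ls.compute_lqaf(images["lqaf_stack"],
                           center_region=lgeo["center_region"],
                           ref_region=lgeo["ref_region"],
                           scale=gen.lqaf_score_scale)
    acoct = ls.compute_acoct_reflectivity(images["acoct"],
                                          images["acoct_rois"]["cornea"],
                                          images["acoct_rois"]["lens"],
                                          scale=gen.acoct_score_scale)
    pns = ls.compute_pns(images["scheimpflug"], images["nucleus_mask"],
                         gen.pns_grade_edges)
    qaf_pre = qr.qaf8_from_frames(images["qaf_frames"], geometry,
                                  scale_k=gen.qaf_ref_level)
    out = {"lqaf": lqaf, "acoct_reflectivity": acoct,
           "pns_grade": pns["grade"], "pns_mean_density": pns["mean"],
           "pns_sd_density": pns["sd"], "pns_max_density": pns["max"],
           "qaf8_pre": qaf_pre.ring_mean,
           "snr": reference_snr(images["qaf_frames"], geometry)}
    if "qaf_frames_post" in images:
        out["qaf8_post"] = qr.qaf8_from_frames(images["qaf_frames_post"],
                                               geometry,
                                               scale_k=gen.qaf_ref_level).ring_mean
    return out


# ---------------------------------------------------------------------------
# the full study
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    mae_agebase: float
    sd_agebase: float
    mae_spline: float
    sd_spline: float
    mae_spline_cv: float
    sd_spline_cv: float
    cv_r2_lasso: float
    r2_linear_lqaf: float
    deviance_explained: float
    r2_spline: float
    lasso_selected: list
    elimination_order: list
    n_subjects: int
    n_surgery: int
    n_excluded: int
    seed: int
    config_digest: str
    extras: dict = field(default_factory=dict)

    def to_json(self, indent=2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True)


def _spline_response(df: pd.DataFrame) -> np.ndarray:
    """Post-surgery QAF where measured, ground-truth QAF otherwise."""
    return np.where(df["qaf8_post"].notna(), df["qaf8_post"], df["qaf8_true"])


def run_study(cfg: StudyConfig | None = None, seed: int = 0,
              out_dir=None) -> EvaluationReport:
    """Run the full synthetic study and return the comparison report.

    Stages: cohort generation -> (optional) image rendering and score
    extraction -> exclusion by reference SNR -> LASSO + LOO-CV and backward
    selection on the surgery subset -> varying-coefficient spline fit ->
    age-based vs spline MAE against post-surgery QAF.
    """
    cfg = cfg or StudyConfig()
    records = syn.generate_cohort(cfg.n, cfg.surgery_n, seed, cfg.generator,
                                  cfg.scheimpflug_shape)
    rows = []
    for rec in records:
        try:
            row = {"subject_id": rec.subject_id, "age": rec.age,
                   "phakic": rec.phakic, "qaf8_true": rec.qaf8_true}
            if cfg.render:
                images = render_subject_images(rec, seed, cfg)
                meas = score_subject(rec, images, cfg)
                row.update(meas)
                row.setdefault("qaf8_post", np.nan)
                if rec.qaf8_post is None:
                    row["qaf8_post"] = np.nan
            else:
                row.update(rec.scores)
                row["qaf8_pre"] = rec.qaf8_pre
                row["qaf8_post"] = rec.qaf8_post if rec.qaf8_post is not None \
                    else np.nan
                row["snr"] = np.inf
        except Exception as exc:
            raise RuntimeError(
                f"study stage 'render/score' failed for subject "
                f"{rec.subject_id}: {exc}") from exc
        rows.append(row)
    df = pd.DataFrame(rows)
    included = df[df["snr"] >= cfg.snr_threshold].reset_index(drop=True)
    n_excluded = int(len(df) - len(included))
    surgery = included[included["qaf8_post"].notna()].reset_index(drop=True)
    if len(surgery) < 5:
        raise RuntimeError("study stage 'selection': fewer than 5 surgery "
                           "subjects after exclusions")

    # --- LASSO + LOO-CV and backward selection on the surgery subset
    X = surgery[LASSO_PREDICTORS].to_numpy(float)
    if cfg.lasso_response == "post":
        y_sel = surgery["qaf8_post"].to_numpy(float)
    elif cfg.lasso_response == "diff":
        y_sel = (surgery["qaf8_pre"] - surgery["qaf8_post"]).to_numpy(float)
    else:
        raise ValueError(f"unknown lasso_response {cfg.lasso_response!r}")
    Z, _, _ = models.standardize_predictors(X, LASSO_PREDICTORS)
    path = models.fit_lasso_path(Z, y_sel, names=LASSO_PREDICTORS)
    models.loo_cv_select(Z, y_sel, path)
    back = models.backward_select(X, y_sel, names=LASSO_PREDICTORS)

    # --- varying-coefficient spline model on the full included cohort
    y_spline = _spline_response(included)
    fit = models.fit_spline_model(included["age"], included["lqaf"],
                                  included["pns_grade"], y_spline,
                                  cfg.spline)

    # --- age-based baseline vs spline predictions on the surgery subset
    spec = models.AgeCorrectionSpec.from_config(cfg.agecorrection)
    agebase = models.age_based_estimate(surgery["qaf8_pre"].to_numpy(float),
                                        surgery["age"].to_numpy(float),
                                        surgery["phakic"].to_numpy(bool), spec)
    post = surgery["qaf8_post"].to_numpy(float)
    mae_age, sd_age = compute_mae(agebase, post)
    pred_in = np.atleast_1d(models.predict_qaf(fit, surgery["age"],
                                               surgery["lqaf"],
                                               surgery["pns_grade"]))
    mae_sp, sd_sp = compute_mae(pred_in, post)
    pred_cv = _loo_spline_predictions(included, surgery, cfg)
    mae_cv, sd_cv = compute_mae(pred_cv, post)
    r2_lin = linear_r2(included["lqaf"], included["qaf8_pre"])

    report = EvaluationReport(
        mae_agebase=mae_age, sd_agebase=sd_age,
        mae_spline=mae_sp, sd_spline=sd_sp,
        mae_spline_cv=mae_cv, sd_spline_cv=sd_cv,
        cv_r2_lasso=float(path.cv_r2),
        r2_linear_lqaf=r2_lin,
        deviance_explained=fit.deviance_explained,
        r2_spline=fit.r2,
        lasso_selected=list(path.selected_variables),
        elimination_order=list(back["elimination_order"]),
        n_subjects=int(len(included)), n_surgery=int(len(surgery)),
        n_excluded=n_excluded, seed=int(seed), config_digest=cfg.digest(),
        extras={
            "lqaf_mean": float(included["lqaf"].mean()),
            "acoct_mean": float(included["acoct_reflectivity"].mean()),
            "age_mean": float(included["age"].mean()),
            "pns_grade_mean": float(included["pns_grade"].mean()),
            "term_tests": {k: {kk: float(vv) for kk, vv in v.items()}
                           for k, v in fit.term_tests.items()},
            "backward_final_set": back["final_set"],
            "spline_intercept": fit.intercept,
        })
    if out_dir is not None:
        _write_outputs(out_dir, cfg, df, included, report)
    return report


def _loo_spline_predictions(included: pd.DataFrame, surgery: pd.DataFrame,
                            cfg: StudyConfig) -> np.ndarray:
    """Cross-validated spline predictions: refit without each surgery subject
    and predict it from the model it did not train."""
    preds = np.empty(len(surgery))
    ids = set(surgery["subject_id"])
    for k, (_, row) in enumerate(surgery.iterrows()):
        train = included[included["subject_id"] != row["subject_id"]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = models.fit_spline_model(train["age"], train["lqaf"],
                                          train["pns_grade"],
                                          _spline_response(train), cfg.spline)
            preds[k] = models.predict_qaf(fit, row["age"], row["lqaf"],
                                          row["pns_grade"])
    return preds


def _write_outputs(out_dir, cfg: StudyConfig, df: pd.DataFrame,
                   included: pd.DataFrame, report: EvaluationReport) -> None:
    import pathlib
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "cohort_measured.csv", index=False)
    included.to_csv(out / "cohort_included.csv", index=False)
    (out / "report.json").write_text(report.to_json())
    lines = [
        "# Synthetic QAF lens-correction study",
        f"- seed: {report.seed}, config digest: {report.config_digest}",
        f"- subjects: {report.n_subjects} included "
        f"({report.n_excluded} excluded), surgery subset: {report.n_surgery}",
        f"- age-based correction: MAE {report.mae_agebase:.1f} "
        f"± {report.sd_agebase:.1f} a.u.",
        f"- spline model (in-sample): MAE {report.mae_spline:.1f} "
        f"± {report.sd_spline:.1f} a.u.",
        f"- spline model (cross-validated): MAE {report.mae_spline_cv:.1f} "
        f"± {report.sd_spline_cv:.1f} a.u.",
        f"- LASSO: cv R² {report.cv_r2_lasso:.2f}, "
        f"selected {report.lasso_selected}",
        f"- backward elimination order: {report.elimination_order}",
        f"- spline fit: R² {report.r2_spline:.2f}, deviance explained "
        f"{100 * report.deviance_explained:.1f}%",
        f"- linear LQAF→QAF R²: {report.r2_linear_lqaf:.2f}",
    ]
    (out / "report.md").write_text("\n".join(lines) + "\n")
    cfg.to_yaml(out / "study_config.yaml")
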