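"""Correction models.

The statistical core of the pipeline:

* predictor standardization (mean 0, SD 1, n-1 denominator);
* L1-penalized (LASSO) linear regression solved by cyclic coordinate descent
  over a 100-value descending lambda path, with leave-one-out cross-validation
  for the penalty choice;
* backward variable elimination under a leave-one-out MSE criterion;
* the classical age-based lens correction factor (phakic eyes only);
* a penalized varying-coefficient spline model
  ``y = b0 + f1(age) + LQAF * f2(age) + PNS * f3(age)``
  with cubic B-spline bases, second-derivative penalties, GCV-selected
  smoothing parameters, effective degrees of freedom and Wald-type smooth-term
  tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import null_space

from .config import AgeCorrectionConfig, SplineConfig


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize_predictors(X: np.ndarray, names: Sequence[str] | None = None):
    """Mean-center and scale each column to unit SD (n-1 denominator).

    Returns ``(Z, means, sds)``; the inverse transform is
    ``X = Z * sds + means``.  A zero-variance column raises, naming it.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n x p)")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    for j, s in enumerate(sds):
        if not s > 0:
            label = names[j] if names is not None else f"column {j}"
            raise ValueError(f"predictor {label} has zero variance")
    return (X - means) / sds, means, sds


# ---------------------------------------------------------------------------
# LASSO: coordinate descent over a lambda path
# ---------------------------------------------------------------------------

@dataclass
class LassoPath:
    lambda_grid: np.ndarray          # 100 descending penalties
    coef_matrix: np.ndarray          # (n_lambdas, p), standardized scale
    intercepts: np.ndarray
    names: Optional[list] = None
    loocv_error: Optional[np.ndarray] = None
    selected_lambda: Optional[float] = None
    selected_variables: Optional[list] = None
    cv_r2: Optional[float] = None


def _cd_solve(Z, y, lam, beta0, tol=1e-9, max_sweeps=100_000):
    """Cyclic coordinate descent for
    (1/2n)||y - b0 - Z b||^2 + lam * ||b||_1, intercept unpenalized."""
    n, p = Z.shape
    ybar = y.mean()
    zbar = Z.mean(axis=0)
    Zc = Z - zbar
    yc = y - ybar
    v = (Zc * Zc).sum(axis=0) / n
    beta = beta0.copy()
    r = yc - Zc @ beta
    for sweep in range(max_sweeps):
        delta = 0.0
        for j in range(p):
            bj = beta[j]
            rho = Zc[:, j] @ r / n + v[j] * bj
            # relative guard so |rho| == lam (up to rounding) yields exactly 0
            excess = abs(rho) - lam
            if excess <= 1e-12 * max(1.0, abs(rho)):
                bnew = 0.0
            else:
                bnew = np.sign(rho) * excess / v[j]
            if bnew != bj:
                r += Zc[:, j] * (bj - bnew)
                beta[j] = bnew
                delta = max(delta, abs(bnew - bj))
        if delta < tol:
            break
    else:
        raise RuntimeError(f"coordinate descent did not converge at lambda={lam:g}")
    b0 = ybar - zbar @ beta
    return b0, beta


def lambda_max(Z: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which all slope coefficients are exactly zero:
    ``max_j |Z_j^T (y - ybar)| / n``."""
    n = len(y)
    Zc = Z - Z.mean(axis=0)
    return float(np.max(np.abs(Zc.T @ (y - y.mean()))) / n)


def fit_lasso_path(Z: np.ndarray, y: np.ndarray, n_lambdas: int = 100,
                   names: Sequence[str] | None = None,
                   lambda_min_ratio: float = 1e-6) -> LassoPath:
    """Fit the LASSO along a log-spaced descending lambda path with warm starts.

    The path runs from ``lambda_max`` (all slopes zero) down to
    ``lambda_max * lambda_min_ratio``, a proxy for the ordinary-least-squares
    end of the path.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(Z)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in the design or response")
    n, p = Z.shape
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    lmax = lambda_max(Z, y)
    grid = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambdas)
    coefs = np.zeros((n_lambdas, p))
    intercepts = np.zeros(n_lambdas)
    beta = np.zeros(p)
    for i, lam in enumerate(grid):
        b0, beta = _cd_solve(Z, y, lam, beta)
        intercepts[i], coefs[i] = b0, beta
    return LassoPath(lambda_grid=grid, coef_matrix=coefs, intercepts=intercepts,
                     names=list(names) if names is not None else None)


def kkt_violation(Z: np.ndarray, y: np.ndarray, intercept: float,
                  beta: np.ndarray, lam: float) -> float:
    """Maximum violation of the LASSO subgradient (KKT) conditions:
    for zero coefficients ``|Z_j^T r / n| <= lam``; for active ones
    ``Z_j^T r / n = lam * sign(beta_j)``."""
    n = len(y)
    r = y - intercept - Z @ beta
    g = Z.T @ r / n
    viol = 0.0
    for j, bj in enumerate(beta):
        if bj == 0.0:
            viol = max(viol, abs(g[j]) - lam)
        else:
            viol = max(viol, abs(g[j] - lam * np.sign(bj)))
    return float(viol)


def loo_cv_select(Z: np.ndarray, y: np.ndarray, path: LassoPath):
    """Leave-one-out CV along the path: n refits per lambda; selects the
    lambda minimizing LOO-MSE and reports ``cv_r2 = 1 - LOO-MSE / var(y)``.

    Mutates ``path`` in place (loocv_error, selected_lambda,
    selected_variables, cv_r2) and returns
    ``(selected_lambda, selected_variables, cv_r2)``.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Z.shape
    if n < 3:
        raise ValueError("need at least 3 observations for leave-one-out CV")
    errors = np.zeros(len(path.lambda_grid))
    mask = np.ones(n, dtype=bool)
    for il, lam in enumerate(path.lambda_grid):
        sq = 0.0
        for i in range(n):
            mask[i] = False
            b0, beta = _cd_solve(Z[mask], y[mask], lam, path.coef_matrix[il].copy())
            sq += (y[i] - b0 - Z[i] @ beta) ** 2
            mask[i] = True
        errors[il] = sq / n
    best = int(np.argmin(errors))
    path.loocv_error = errors
    path.selected_lambda = float(path.lambda_grid[best])
    nz = np.flatnonzero(path.coef_matrix[best])
    path.selected_variables = ([path.names[j] for j in nz] if path.names
                               else list(nz))
    path.cv_r2 = float(1.0 - errors[best] / np.var(y))
    return path.selected_lambda, path.selected_variables, path.cv_r2


# ---------------------------------------------------------------------------
# backward selection under leave-one-out MSE
# ---------------------------------------------------------------------------

def _ols_loo_mse(X: np.ndarray, y: np.ndarray) -> float:
    """Exact leave-one-out MSE of OLS-with-intercept via the hat-matrix
    identity ``e_loo_i = r_i / (1 - h_ii)``."""
    n = len(y)
    X1 = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    r = y - X1 @ beta
    # h_ii = x_i^T (X^T X)^-1 x_i
    G = np.linalg.pinv(X1.T @ X1)
    h = np.einsum("ij,jk,ik->i", X1, G, X1)
    return float(np.mean((r / (1.0 - h)) ** 2))


def backward_select(X: np.ndarray, y: np.ndarray,
                    names: Sequence[str] | None = None) -> dict:
    """Backward elimination: iteratively remove the variable whose removal
    most improves the leave-one-out MSE; stop when no removal improves it.

    Ties are broken by removing the variable with the smaller absolute
    standardized OLS coefficient.  Returns the ordered elimination log, the
    final variable set, and the criterion value at each step.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("backward selection needs at least 2 predictors")
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    active = list(range(p))
    current = _ols_loo_mse(X, y)
    order, log = [], [{"step": 0, "removed": None, "loo_mse": current}]
    while len(active) > 1:
        cand = [(_ols_loo_mse(X[:, [k for k in active if k != j]], y), j)
                for j in active]
        best_mse = min(c[0] for c in cand)
        ties = [j for mse, j in cand if mse <= best_mse + 1e-12 * (1 + best_mse)]
        if len(ties) > 1:
            Zs, _, _ = standardize_predictors(X[:, active])
            beta, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(n), Zs]), y, rcond=None)
            coef = dict(zip(active, np.abs(beta[1:])))
            drop = min(ties, key=lambda j: coef[j])
        else:
            drop = ties[0]
        if best_mse >= current:
            break
        active.remove(drop)
        order.append(names[drop])
        current = best_mse
        log.append({"step": len(order), "removed": names[drop],
                    "loo_mse": current})
    return {"elimination_order": order,
            "final_set": [names[j] for j in active],
            "log": log}


# ---------------------------------------------------------------------------
# age-based correction factor
# ---------------------------------------------------------------------------

@dataclass
class AgeCorrectionSpec:
    """Age-only lens correction factor CF(age) >= 1, applied to phakic eyes.

    ``form='loglinear'``: ``CF = max(1, 10**(c0 + c1*(age - age_ref)))``.
    ``form='table'``: monotone lookup table interpolated linearly.
    """

    form: str = "loglinear"
    c0: float = 0.1040
    c1: float = 0.01766
    age_ref: float = 63.0
    table_ages: Optional[np.ndarray] = None
    table_factors: Optional[np.ndarray] = None
    age_domain: tuple = (18.0, 100.0)

    @classmethod
    def from_config(cls, cfg: AgeCorrectionConfig) -> "AgeCorrectionSpec":
        return cls(form="loglinear", c0=cfg.c0, c1=cfg.c1, age_ref=cfg.age_ref,
                   age_domain=tuple(cfg.age_domain))

    def factor(self, age):
        age = np.asarray(age, dtype=float)
        lo, hi = self.age_domain
        if np.any(age < lo) or np.any(age > hi):
            raise ValueError(f"age outside the correction domain [{lo}, {hi}]")
        if self.form == "loglinear":
            cf = 10.0 ** (self.c0 + self.c1 * (age - self.age_ref))
        elif self.form == "table":
            if self.table_ages is None or self.table_factors is None:
                raise ValueError("table form requires table_ages/table_factors")
            cf = np.interp(age, self.table_ages, self.table_factors)
        else:
            raise ValueError(f"unknown correction form {self.form!r}")
        return np.maximum(cf, 1.0)


def age_based_estimate(qaf_measured, age, phakic, spec: AgeCorrectionSpec):
    """Classical age-only correction: ``measured * CF(age)`` for phakic eyes,
    the measurement unchanged for pseudophakic eyes."""
    qaf = np.asarray(qaf_measured, dtype=float)
    phakic = np.asarray(phakic, dtype=bool)
    cf = spec.factor(age)
    out = np.where(phakic, qaf * cf, qaf)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# penalized varying-coefficient spline model
# ---------------------------------------------------------------------------

def _bspline_knots(x: np.ndarray, n_basis: int, degree: int) -> np.ndarray:
    """Clamped knot vector with interior knots at quantiles of x."""
    n_interior = n_basis - degree - 1
    if n_interior < 0:
        raise ValueError("n_basis too small for the requested degree")
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(x, qs) if n_interior else np.array([])
    lo, hi = float(x.min()), float(x.max())
    interior = np.clip(interior, lo + 1e-9, hi - 1e-9)
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def _design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    xc = np.clip(x, knots[0], knots[-1])
    return BSpline.design_matrix(xc, knots, degree).toarray()


def _second_derivative_penalty(knots: np.ndarray, degree: int) -> np.ndarray:
    """S_jl = integral of B_j''(x) B_l''(x) dx, by Gauss-Legendre per knot span
    (exact: the integrand is piecewise polynomial of degree 2(degree-2))."""
    nb = len(knots) - degree - 1
    spl = BSpline(knots, np.eye(nb), degree)
    d2 = spl.derivative(2)
    gauss_x, gauss_w = np.polynomial.legendre.leggauss(max(degree, 3))
    S = np.zeros((nb, nb))
    spans = np.unique(knots)
    for a, b in zip(spans[:-1], spans[1:]):
        if b <= a:
            continue
        pts = 0.5 * (b - a) * gauss_x + 0.5 * (a + b)
        w = 0.5 * (b - a) * gauss_w
        V = d2(pts)                      # (npts, nb)
        S += (V * w[:, None]).T @ V
    return S


@dataclass
class SplineModelFit:
    intercept: float
    intercept_se: float
    intercept_t: float
    intercept_p: float
    knots: np.ndarray
    degree: int
    constraint: np.ndarray           # null-space transform for f1 (nb x nb-1)
    coef_f1: np.ndarray              # constrained-scale coefficients
    coef_f2: np.ndarray
    coef_f3: np.ndarray
    smoothing_params: np.ndarray     # (lam1, lam2, lam3)
    edf: dict                        # per-term effective degrees of freedom
    term_tests: dict                 # per-term {edf, ref_df, F, p}
    r2: float                        # adjusted R^2
    deviance_explained: float
    sigma2: float
    rss: float
    edf_total: float
    n: int
    train_ranges: dict
    fitted: np.ndarray
    covariance: np.ndarray           # Bayesian posterior covariance of all coefs
    gcv_boundary_warnings: list = field(default_factory=list)

    TERMS = ("s(age)", "s(age):lqaf", "s(age):pns")


class _VCDesign:
    """Design/penalty assembly shared by fitting and prediction."""

    def __init__(self, age, lqaf, pns, n_basis, degree):
        age = np.asarray(age, float)
        self.knots = _bspline_knots(age, n_basis, degree)
        self.degree = degree
        self.nb = n_basis
        B = _design(age, self.knots, degree)
        C = B.sum(axis=0, keepdims=True)       # sum-to-zero constraint on f1
        self.Z1 = null_space(C)                # (nb, nb-1)
        S = _second_derivative_penalty(self.knots, degree)
        S = S / np.linalg.eigvalsh(S).max()
        self.S_blocks = [self.Z1.T @ S @ self.Z1, S, S]
        self.X = self.assemble(age, np.asarray(lqaf, float), np.asarray(pns, float))
        self.slices = self.block_slices()

    def assemble(self, age, lqaf, pns):
        B = _design(np.asarray(age, float), self.knots, self.degree)
        return np.column_stack([np.ones(len(B)), B @ self.Z1,
                                lqaf[:, None] * B, pns[:, None] * B])

    def block_slices(self):
        p1 = self.nb - 1
        return [slice(1, 1 + p1),
                slice(1 + p1, 1 + p1 + self.nb),
                slice(1 + p1 + self.nb, 1 + p1 + 2 * self.nb)]

    def penalty(self, lams):
        p = self.X.shape[1]
        P = np.zeros((p, p))
        for lam, sl, S in zip(lams, self.slices, self.S_blocks):
            P[sl, sl] = lam * S
        return P

    def penalty_sqrt(self, lams):
        """Stacked square-root penalty rows for augmented least squares."""
        rows = []
        p = self.X.shape[1]
        for lam, sl, S in zip(lams, self.slices, self.S_blocks):
            w, V = np.linalg.eigh(S)
            w = np.clip(w, 0.0, None)
            L = (np.sqrt(lam * w)[:, None] * V.T)
            block = np.zeros((L.shape[0], p))
            block[:, sl] = L
            rows.append(block)
        return np.vstack(rows)

    def solve(self, y, lams):
        aug = np.vstack([self.X, self.penalty_sqrt(lams)])
        rhs = np.concatenate([y, np.zeros(aug.shape[0] - len(y))])
        beta, *_ = np.linalg.lstsq(aug, rhs, rcond=None)
        return beta


def fit_spline_model(age, lqaf, pns, y,
                     config: SplineConfig | None = None) -> SplineModelFit:
    """Fit the varying-coefficient model
    ``y = b0 + f1(age) + lqaf*f2(age) + pns*f3(age)`` by penalized least
    squares with per-term second-derivative penalties.

    Smoothing parameters are chosen by generalized cross-validation over a
    fixed log-spaced grid, coordinate-wise over the three terms; ``f1``
    carries a sum-to-zero identifiability constraint, so the intercept is the
    mean response at average age (for zero lens scores).  Term F statistics
    are Wald-type, using the Bayesian coefficient covariance truncated at the
    rounded effective degrees of freedom.
    """
    cfg = config or SplineConfig()
    age = np.asarray(age, float)
    lqaf = np.asarray(lqaf, float)
    pns = np.asarray(pns, float)
    y = np.asarray(y, float)
    n = len(y)
    if n < 30:
        raise ValueError("spline model needs at least 30 observations")
    if not all(np.all(np.isfinite(v)) for v in (age, lqaf, pns, y)):
        raise ValueError("non-finite values in predictors or response")
    des = _VCDesign(age, lqaf, pns, cfg.n_basis, cfg.degree)
    X = des.X
    # estimability: X must identify the unpenalized (null-space) directions
    if np.linalg.matrix_rank(np.vstack([X, des.penalty_sqrt(np.ones(3))])) \
            < X.shape[1]:
        raise ValueError("degenerate (collinear) spline design: a predictor is "
                         "constant or the terms are confounded")
    XtX = X.T @ X
    Xty = X.T @ y
    grid = np.geomspace(10.0 ** cfg.gcv_log10_min, 10.0 ** cfg.gcv_log10_max,
                        cfg.gcv_grid_size)
    lams = np.ones(3)
    boundary = []
    ranks = [np.linalg.matrix_rank(S, tol=1e-10) for S in des.S_blocks]
    m_null = X.shape[1] - sum(ranks)

    def gcv_of(lams_):
        A = XtX + des.penalty(lams_)
        try:
            beta = np.linalg.solve(A, Xty)
            F = np.linalg.solve(A, XtX)
        except np.linalg.LinAlgError:
            raise ValueError("degenerate (collinear) design in the spline model")
        rss = float(np.sum((y - X @ beta) ** 2))
        tr = float(np.trace(F))
        return n * rss / (n - cfg.gcv_gamma * tr) ** 2

    def reml_of(lams_):
        # Gaussian restricted likelihood with sigma^2 profiled out
        P = des.penalty(lams_)
        A = XtX + P
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            raise ValueError("degenerate (collinear) design in the spline model")
        beta = np.linalg.solve(A, Xty)
        rss_p = float(np.sum((y - X @ beta) ** 2)) + float(beta @ P @ beta)
        logdet_s = sum(r * np.log(l) for r, l in zip(ranks, lams_))
        return (n - m_null) * np.log(rss_p) + logdet_a - logdet_s

    score_of = reml_of if cfg.selector == "reml" else gcv_of
    for _ in range(cfg.gcv_passes):
        for t in range(3):
            scores = []
            for g in grid:
                trial = lams.copy()
                trial[t] = g
                scores.append(score_of(trial))
            k = int(np.argmin(scores))
            lams[t] = grid[k]
            if k in (0, len(grid) - 1):
                boundary.append(
                    f"smoothing grid boundary for {SplineModelFit.TERMS[t]}: "
                    f"lambda={grid[k]:.3g}")
    for msg in set(boundary):
        warnings.warn(msg)

    beta = des.solve(y, lams)
    A = XtX + des.penalty(lams)
    Ainv = np.linalg.inv(A)
    Fmat = Ainv @ XtX
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    edf_total = float(np.trace(Fmat))
    sigma2 = rss / (n - edf_total)
    Vb = Ainv * sigma2
    tss = float(np.sum((y - y.mean()) ** 2))
    edf = {}
    term_tests = {}
    for t, sl in enumerate(des.slices):
        name = SplineModelFit.TERMS[t]
        edf_t = float(np.trace(Fmat[sl, sl]))
        edf[name] = edf_t
        bt = beta[sl]
        Vt = Vb[sl, sl]
        r = int(min(sl.stop - sl.start, max(1, round(edf_t))))
        w, V = np.linalg.eigh(Vt)
        idx = np.argsort(w)[::-1][:r]
        w_r, V_r = w[idx], V[:, idx]
        T = float(bt @ V_r @ np.diag(1.0 / w_r) @ V_r.T @ bt)
        Fstat = T / r
        p = float(stats.f.sf(Fstat, r, n - edf_total))
        term_tests[name] = {"edf": edf_t, "ref_df": float(r), "F": Fstat, "p": p}
    se0 = float(np.sqrt(Vb[0, 0]))
    t0 = float(beta[0] / se0)
    p0 = float(2 * stats.t.sf(abs(t0), n - edf_total))
    dev = 1.0 - rss / tss
    r2_adj = 1.0 - (rss / (n - edf_total)) / (tss / (n - 1))
    return SplineModelFit(
        intercept=float(beta[0]), intercept_se=se0, intercept_t=t0,
        intercept_p=p0, knots=des.knots, degree=des.degree, constraint=des.Z1,
        coef_f1=beta[des.slices[0]].copy(), coef_f2=beta[des.slices[1]].copy(),
        coef_f3=beta[des.slices[2]].copy(), smoothing_params=lams.copy(),
        edf=edf, term_tests=term_tests, r2=float(r2_adj),
        deviance_explained=float(dev), sigma2=float(sigma2), rss=rss,
        edf_total=edf_total, n=n,
        train_ranges={"age": (float(age.min()), float(age.max())),
                      "lqaf": (float(lqaf.min()), float(lqaf.max())),
                      "pns": (float(pns.min()), float(pns.max()))},
        fitted=fitted, covariance=Vb,
        gcv_boundary_warnings=sorted(set(boundary)))


def evaluate_term(fit: SplineModelFit, term: str, ages) -> np.ndarray:
    """Evaluate a fitted smooth function at given ages: ``f1(age)`` for
    ``'s(age)'`` or the varying coefficients ``f2/f3(age)`` for the
    interaction terms."""
    B = _design(np.asarray(ages, float), fit.knots, fit.degree)
    if term == "s(age)":
        return B @ fit.constraint @ fit.coef_f1
    if term == "s(age):lqaf":
        return B @ fit.coef_f2
    if term == "s(age):pns":
        return B @ fit.coef_f3
    raise KeyError(term)


def predict_qaf(fit: SplineModelFit, age, lqaf, pns) -> np.ndarray:
    """Predicted QAF for new observations:
    ``b0 + f1(age) + lqaf*f2(age) + pns*f3(age)``.

    Warns when inputs fall more than 10% of the training span outside the
    training range."""
    if fit.coef_f1 is None:
        raise RuntimeError("model has not been fitted")
    age = np.atleast_1d(np.asarray(age, float))
    lqaf = np.atleast_1d(np.asarray(lqaf, float))
    pns = np.atleast_1d(np.asarray(pns, float))
    for name, v in (("age", age), ("lqaf", lqaf), ("pns", pns)):
        lo, hi = fit.train_ranges[name]
        slack = 0.1 * (hi - lo)
        if np.any(v < lo - slack) or np.any(v > hi + slack):
            warnings.warn(f"{name} outside the training range [{lo:.3g}, {hi:.3g}] "
                          "by more than 10%; extrapolating")
    pred = (fit.intercept + evaluate_term(fit, "s(age)", age)
            + lqaf * evaluate_term(fit, "s(age):lqaf", age)
            + pns * evaluate_term(fit, "s(age):pns", age))
    return pred if pred.size > 1 else float(pred[0])
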