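"""Swarm-level trend models.

Relates ellipsoid volume to the operational sex ratio code via a
quadratic law V(x) = a x^2 + b x + c, fits penalized cubic smoothing
splines S(x) = sum_i alpha_i B_i(x), models mean speed against swarm
density with a random-intercept (per replicate) mixed model, and ranks
linear/quadratic/cubic/logistic/spline candidates by AIC under a
Gaussian likelihood.

AIC convention: AIC = 2k - 2 logL with the Gaussian log-likelihood at
the ML residual variance; k counts mean parameters plus one for the
variance, and for the spline the mean-parameter count is the effective
degrees of freedom, the trace of the smoother matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import curve_fit

from .errors import UnderDeterminedError

__all__ = [
    "QuadraticFit",
    "SplineFit",
    "MixedModelFit",
    "ModelComparison",
    "r_squared",
    "fit_quadratic",
    "fit_spline",
    "fit_mixed_speed_density",
    "compare_models",
    "gaussian_aic",
]

log = logging.getLogger(__name__)


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.size < 2:
        raise UnderDeterminedError("R^2 needs at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UnderDeterminedError("R^2 undefined: zero variance in y")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def gaussian_aic(y: np.ndarray, y_hat: np.ndarray, k: float) -> float:
    """AIC under iid Gaussian residuals with ML variance; k includes the variance."""
    y = np.asarray(y, float)
    n = y.size
    sigma2 = max(float(np.mean((y - np.asarray(y_hat, float)) ** 2)), 1e-300)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return 2.0 * k - 2.0 * loglik


@dataclass(frozen=True)
class QuadraticFit:
    """Least-squares quadratic volume law V(x) = a x^2 + b x + c."""

    a: float
    b: float
    c: float
    r2: float
    fitted_values: np.ndarray
    residuals: np.ndarray
    aic: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        return self.a * x * x + self.b * x + self.c

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])


def fit_quadratic(x: np.ndarray, y: np.ndarray) -> QuadraticFit:
    """Ordinary least squares of y on [x^2, x, 1].

    The quadratic is linear in its coefficients, so the nonlinear
    least-squares optimum coincides with the normal-equations solution
    used here.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.unique(x).size < 3:
        raise UnderDeterminedError("quadratic fit needs >= 3 distinct x values")
    design = np.column_stack([x * x, x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    return QuadraticFit(
        a=float(coef[0]),
        b=float(coef[1]),
        c=float(coef[2]),
        r2=r_squared(y, fitted),
        fitted_values=fitted,
        residuals=y - fitted,
        aic=gaussian_aic(y, fitted, k=4),
    )


@dataclass(frozen=True)
class SplineFit:
    """Penalized cubic B-spline fit with roughness penalty on the second derivative."""

    knots: np.ndarray
    coefficients: np.ndarray
    order: int
    smoothing: float
    edf: float  # trace of the smoother matrix
    r2: float
    aic: float
    fitted_values: np.ndarray
    _bspline: BSpline = field(repr=False, compare=False, default=None)

    def predict(self, x) -> np.ndarray:
        return self._bspline(np.asarray(x, float))


def _bspline_design(x: np.ndarray, knots_interior: np.ndarray, degree: int):
    lo, hi = x.min(), x.max()
    t = np.concatenate([[lo] * (degree + 1), knots_interior, [hi] * (degree + 1)])
    n_basis = len(t) - degree - 1
    design = BSpline.design_matrix(x, t, degree, extrapolate=True).toarray()
    return t, n_basis, design


def _second_derivative_penalty(t: np.ndarray, n_basis: int, degree: int) -> np.ndarray:
    """Exact Gram matrix of second derivatives of the B-spline basis.

    For cubic splines the second derivatives are piecewise linear, so
    two-point Gauss-Legendre per knot span integrates their products
    exactly.
    """
    omega = np.zeros((n_basis, n_basis))
    # Gauss-Legendre nodes/weights on [-1, 1]
    gl_x = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    gl_w = np.array([1.0, 1.0])
    spans = np.unique(t)
    basis = [
        BSpline(t, np.eye(n_basis)[i], degree, extrapolate=False) for i in range(n_basis)
    ]
    d2 = [b.derivative(2) for b in basis]
    for a, b in zip(spans[:-1], spans[1:]):
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        for xg, wg in zip(gl_x, gl_w):
            xi = mid + half * xg
            vals = np.array([np.nan_to_num(f(xi)) for f in d2])
            omega += (wg * half) * np.outer(vals, vals)
    return omega


def fit_spline(
    x: np.ndarray,
    y: np.ndarray,
    order: int = 3,
    smoothing: float | str = "gcv",
) -> SplineFit:
    """Fit a penalized cubic regression spline with interior knots at the
    interior data sites.

    ``smoothing`` is the roughness-penalty weight lambda; the default
    "gcv" selects it by generalized cross-validation over a log grid
    (including the near-interpolating limit). The effective degrees of
    freedom is the trace of the smoother matrix
    H = B (B'B + lambda * Omega)^-1 B'.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < order + 2:
        raise UnderDeterminedError(f"spline fit needs >= {order + 2} points, got {x.size}")
    srt = np.argsort(x, kind="stable")
    xs, ys = x[srt], y[srt]
    interior = np.unique(xs)[1:-1]
    t, n_basis, B = _bspline_design(xs, interior, order)
    omega = _second_derivative_penalty(t, n_basis, order)
    btb = B.T @ B
    bty = B.T @ ys

    def solve(lam: float):
        A = btb + lam * omega + 1e-12 * np.trace(btb) / n_basis * np.eye(n_basis)
        coef = np.linalg.solve(A, bty)
        hat_diag_sum = float(np.trace(B @ np.linalg.solve(A, B.T)))
        return coef, hat_diag_sum

    if smoothing == "gcv":
        scale = float(np.trace(btb)) / max(float(np.trace(omega)), 1e-30)
        grid = scale * np.logspace(-8, 2, 31)
        best = (np.inf, None, None)
        n = xs.size
        for lam in grid:
            coef, edf = solve(lam)
            if edf > 0.9 * n:  # GCV is degenerate at the interpolating limit
                continue
            resid = ys - B @ coef
            gcv = n * float(resid @ resid) / (n - edf) ** 2
            if gcv < best[0]:
                best = (gcv, lam, (coef, edf))
        if best[1] is None:  # all candidates near-interpolating (tiny n)
            lam = grid[-1]
            coef, edf = solve(lam)
            best = (np.inf, lam, (coef, edf))
        _, lam, (coef, edf) = best
    else:
        lam = float(smoothing)
        coef, edf = solve(lam)

    fitted = B @ coef
    fitted_orig = np.empty_like(fitted)
    fitted_orig[srt] = fitted
    spline = BSpline(t, coef, order, extrapolate=True)
    return SplineFit(
        knots=t,
        coefficients=coef,
        order=order,
        smoothing=lam,
        edf=edf,
        r2=r_squared(y, fitted_orig),
        aic=gaussian_aic(y, fitted_orig, k=edf + 1),
        fitted_values=fitted_orig,
        _bspline=spline,
    )


@dataclass(frozen=True)
class MixedModelFit:
    """Random-intercept model: speed ~ intercept + slope * density + (1 | replicate)."""

    intercept: float
    slope: float
    slope_se: float
    random_intercept_var: float
    resid_var: float
    pseudo_r2: float  # Nakagawa marginal: fixed-effect variance / total
    aic: float
    n_obs: int
    n_groups: int
    converged: bool = True
    fallback_ols: bool = False

    def predict(self, density) -> np.ndarray:
        """Population-level (fixed-effects) prediction of mean speed (m/s)."""
        return self.intercept + self.slope * np.asarray(density, float)


def fit_mixed_speed_density(
    density: np.ndarray,
    mean_speed: np.ndarray,
    replicate_id: np.ndarray,
) -> MixedModelFit:
    """Fit mean speed on swarm density with a random intercept per replicate.

    Gaussian response with identity link. With a single replicate the
    model is unidentifiable and the fit falls back to ordinary least
    squares with a logged warning (random-intercept variance 0).
    """
    import statsmodels.api as sm

    density = np.asarray(density, float)
    mean_speed = np.asarray(mean_speed, float)
    replicate_id = np.asarray(replicate_id)
    if mean_speed.size < 5:
        raise UnderDeterminedError("mixed model needs >= 5 observations")
    exog = sm.add_constant(density)
    groups, counts = np.unique(replicate_id, return_counts=True)

    if groups.size < 2:
        log.warning("single replicate: falling back to ordinary least squares")
        ols = sm.OLS(mean_speed, exog).fit()
        fitted = ols.fittedvalues
        resid_var = float(np.mean(ols.resid**2))
        var_f = float(np.var(fitted))
        return MixedModelFit(
            intercept=float(ols.params[0]),
            slope=float(ols.params[1]),
            slope_se=float(ols.bse[1]),
            random_intercept_var=0.0,
            resid_var=resid_var,
            pseudo_r2=var_f / (var_f + resid_var),
            aic=float(ols.aic),
            n_obs=int(mean_speed.size),
            n_groups=1,
            fallback_ols=True,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(mean_speed, exog, groups=replicate_id)
        res = model.fit(reml=False)
    var_re = float(np.asarray(res.cov_re)[0, 0])
    var_resid = float(res.scale)
    fixed_pred = exog @ res.fe_params
    var_f = float(np.var(fixed_pred))
    pseudo = var_f / (var_f + var_re + var_resid)
    return MixedModelFit(
        intercept=float(res.fe_params[0]),
        slope=float(res.fe_params[1]),
        slope_se=float(res.bse_fe[1]),
        random_intercept_var=var_re,
        resid_var=var_resid,
        pseudo_r2=pseudo,
        aic=float(res.aic),
        n_obs=int(mean_speed.size),
        n_groups=int(groups.size),
        converged=bool(res.converged),
    )


def _logistic4(x, bottom, top, x_mid, hill):
    # 4-parameter logistic; x >= 0 expected (OSR codes)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        z = np.where(x > 0, (x / x_mid) ** hill, 0.0)
    return top + (bottom - top) / (1.0 + z)


@dataclass(frozen=True)
class ModelComparison:
    """Candidates ranked ascending by AIC; `winner` has the lowest AIC."""

    entries: list[dict]  # {"name", "aic", "r2", "k"}
    skipped: list[str]

    @property
    def winner(self) -> str:
        return self.entries[0]["name"]


def compare_models(
    x: np.ndarray,
    y: np.ndarray,
    candidates: tuple[str, ...] = ("linear", "quadratic", "cubic", "logistic", "spline"),
) -> ModelComparison:
    """Fit each candidate trend and rank by Gaussian AIC.

    Saturated candidates (mean parameters >= n) are skipped and flagged,
    as is a logistic fit that fails to converge; neither is fatal. Ties
    keep the input candidate order (stable sort).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    entries: list[dict] = []
    skipped: list[str] = []
    poly_deg = {"linear": 1, "quadratic": 2, "cubic": 3}
    for name in candidates:
        try:
            if name in poly_deg:
                deg = poly_deg[name]
                if deg + 2 >= n:  # mean params + variance >= n
                    skipped.append(f"{name}: saturated (k={deg + 2} >= n={n})")
                    continue
                coef = np.polyfit(x, y, deg)
                fitted = np.polyval(coef, x)
                k = deg + 2
            elif name == "logistic":
                if n <= 5:
                    skipped.append(f"logistic: saturated (k=4 >= usable n={n - 1})")
                    continue
                p0 = [y[np.argmin(x)], y[np.argmax(x)], max(np.median(x[x > 0]), 1.0), 1.0]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(
                        _logistic4,
                        x,
                        y,
                        p0=p0,
                        bounds=([-np.inf, -np.inf, 1e-9, 1e-3], [np.inf, np.inf, np.inf, 50.0]),
                        maxfev=20000,
                    )
                fitted = _logistic4(x, *popt)
                k = 5
            elif name == "spline":
                sfit = fit_spline(x, y)
                fitted, k = sfit.fitted_values, sfit.edf + 1
            else:
                skipped.append(f"{name}: unknown candidate")
                continue
            entries.append(
                {"name": name, "aic": gaussian_aic(y, fitted, k), "r2": r_squared(y, fitted), "k": k}
            )
        except (RuntimeError, UnderDeterminedError, np.linalg.LinAlgError) as exc:
            skipped.append(f"{name}: {exc}")
    if not entries:
        raise UnderDeterminedError("no candidate model could be fitted")
    entries.sort(key=lambda e: e["aic"])
    return ModelComparison(entries=entries, skipped=skipped)
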