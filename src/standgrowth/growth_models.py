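"""Growth-curve forms and their fitters.

Eight basic one-predictor forms are supported, the classic curve-estimation
catalogue for height–diameter and age–diameter allometry:

========  ==========================================
linear       y = b0 + b1·x
logarithmic  y = b0 + b1·ln x
reciprocal   y = b0 + b1/x
quadratic    y = b0 + b1·x + b2·x²
cubic        y = b0 + b1·x + b2·x² + b3·x³
s_curve      y = exp(b0 + b1/x)
growth       y = exp(b0 + b1·x)
logistic     y = b1 / (1 + exp(−b2·(x − b3)))
========  ==========================================

Each form has a multivariate extension with additive covariate terms
appended after the base parameters: inside the exponent for s_curve/growth,
inside the denominator for logistic, and as extra linear terms otherwise.
Setting every covariate coefficient to zero reduces a multivariate form to
its basic counterpart exactly.

Fitting follows the curve-estimation convention: forms linear in their
parameters after a transform (all but logistic) are solved by OLS on the
transformed design — s_curve and growth regress ln y, and their reported
R² is tagged ``fit_scale='log'``.  The logistic form, and optionally any
form, is fitted by trust-region nonlinear least squares on the original
response scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import (
    DomainError,
    SingularDesignError,
    UndefinedR2Error,
)

#: catalogue order; also the tie-break order everywhere
FAMILIES = (
    "linear",
    "logarithmic",
    "reciprocal",
    "quadratic",
    "cubic",
    "s_curve",
    "growth",
    "logistic",
)

_N_BASE_PARAMS = {
    "linear": 2,
    "logarithmic": 2,
    "reciprocal": 2,
    "quadratic": 3,
    "cubic": 4,
    "s_curve": 2,
    "growth": 2,
    "logistic": 3,
}

#: families whose basic form is linear in parameters after a transform
LINEARIZABLE = tuple(f for f in FAMILIES if f != "logistic")

#: families fitted on ln y
LOG_SCALE_FAMILIES = ("s_curve", "growth")

#: penalty prediction for infeasible parameter points (logistic denominator <= 0)
_PENALTY = 1e6


@dataclass(frozen=True)
class ModelForm:
    """One of the 16 declared curve forms.

    ``n_covariates == 0`` is a basic form; otherwise the multivariate
    extension with that many appended covariate predictors.
    """

    family: str
    n_covariates: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_covariates < 0:
            raise ValueError("n_covariates must be >= 0")

    @property
    def n_base_params(self) -> int:
        return _N_BASE_PARAMS[self.family]

    @property
    def n_params(self) -> int:
        return self.n_base_params + self.n_covariates

    @property
    def n_predictors(self) -> int:
        return 1 + self.n_covariates

    @property
    def has_intercept(self) -> bool:
        return self.family != "logistic"

    @property
    def n_terms(self) -> int:
        """Number of non-intercept parameters (df1 of the F test)."""
        return self.n_params - (1 if self.has_intercept else 0)

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.family == "logistic":
            base = ("b1", "b2", "b3")
            start = 4
        else:
            base = tuple(f"b{i}" for i in range(self.n_base_params))
            start = self.n_base_params
        return base + tuple(f"b{start + j}" for j in range(self.n_covariates))

    @property
    def form_id(self) -> str:
        kind = "multivariate" if self.n_covariates else "basic"
        return f"{kind}_{self.family}"

    @property
    def formula(self) -> str:
        cov = "".join(
            f" + {n}·x{j + 2}"
            for j, n in enumerate(self.param_names[self.n_base_params:])
        )
        body = {
            "linear": "b0 + b1·x1",
            "logarithmic": "b0 + b1·ln(x1)",
            "reciprocal": "b0 + b1/x1",
            "quadratic": "b0 + b1·x1 + b2·x1²",
            "cubic": "b0 + b1·x1 + b2·x1² + b3·x1³",
            "s_curve": "b0 + b1/x1",
            "growth": "b0 + b1·x1",
        }
        if self.family in ("s_curve", "growth"):
            return f"y = exp({body[self.family]}{cov})"
        if self.family == "logistic":
            return f"y = b1 / (1 + exp(−b2·(x1 − b3)){cov})"
        return f"y = {body[self.family]}{cov}"


def _as_matrix(form: ModelForm, predictors) -> np.ndarray:
    """Coerce predictors to an (n, 1 + n_covariates) float matrix."""
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None] if form.n_covariates == 0 else X[None, :]
    if X.shape[1] != form.n_predictors:
        raise ValueError(
            f"{form.form_id} expects {form.n_predictors} predictors, "
            f"got {X.shape[1]}"
        )
    return X


def predict(form: ModelForm, params, predictors, *, check_domain: bool = True):
    """Evaluate a curve form.

    Parameters
    ----------
    form, params : the form and its coefficient vector (base parameters
        first, covariate coefficients appended).
    predictors : array of shape (n,) for basic forms or (n, 1+n_covariates).
    check_domain : raise :class:`DomainError` on x1 <= 0 for forms that
        need it.  Non-finite *results* are returned as computed (callers
        flag them); infeasible logistic denominators yield a large penalty
        value rather than a crash.
    """
    params = np.asarray(params, dtype=float)
    if params.size != form.n_params:
        raise ValueError(
            f"{form.form_id} takes {form.n_params} parameters, got {params.size}"
        )
    X = _as_matrix(form, predictors)
    x1 = X[:, 0]
    if check_domain and form.family in ("logarithmic", "reciprocal", "s_curve"):
        if np.any(x1 <= 0):
            raise DomainError(f"{form.family} requires x1 > 0")
    k = form.n_base_params
    cov_term = X[:, 1:] @ params[k:] if form.n_covariates else 0.0
    f = form.family
    with np.errstate(over="ignore", invalid="ignore"):
        if f == "linear":
            return params[0] + params[1] * x1 + cov_term
        if f == "logarithmic":
            return params[0] + params[1] * np.log(x1) + cov_term
        if f == "reciprocal":
            return params[0] + params[1] / x1 + cov_term
        if f == "quadratic":
            return params[0] + params[1] * x1 + params[2] * x1**2 + cov_term
        if f == "cubic":
            return (params[0] + params[1] * x1 + params[2] * x1**2
                    + params[3] * x1**3 + cov_term)
        if f == "s_curve":
            return np.exp(params[0] + params[1] / x1 + cov_term)
        if f == "growth":
            return np.exp(params[0] + params[1] * x1 + cov_term)
        # logistic: covariate terms sit inside the denominator
        denom = 1.0 + np.exp(-params[1] * (x1 - params[2])) + cov_term
        out = np.where(
            np.isfinite(denom) & (denom > 1e-12),
            params[0] / np.where(denom > 1e-12, denom, 1.0),
            _PENALTY,
        )
        return out


def linear_basis(form: ModelForm, predictors) -> tuple[np.ndarray, bool]:
    """Design matrix of a linearizable form (transformed predictors).

    Returns (design, log_response): the OLS design including the intercept
    column, and whether the response must be log-transformed.
    """
    if form.family not in LINEARIZABLE:
        raise ValueError(f"{form.family} is not linearizable")
    X = _as_matrix(form, predictors)
    x1 = X[:, 0]
    if np.any(x1 <= 0) and form.family in ("logarithmic", "reciprocal", "s_curve"):
        raise DomainError(f"{form.family} requires x1 > 0")
    ones = np.ones_like(x1)
    cols = {
        "linear": [ones, x1],
        "logarithmic": [ones, np.log(x1)],
        "reciprocal": [ones, 1.0 / x1],
        "quadratic": [ones, x1, x1**2],
        "cubic": [ones, x1, x1**2, x1**3],
        "s_curve": [ones, 1.0 / x1],
        "growth": [ones, x1],
    }[form.family]
    design = np.column_stack(cols + [X[:, 1 + j] for j in range(form.n_covariates)])
    return design, form.family in LOG_SCALE_FAMILIES


@dataclass
class FitResult:
    """A fitted form plus its goodness of fit on the fitting scale."""

    form: ModelForm
    params: np.ndarray
    r2: float
    f_value: float
    df1: int
    df2: int
    p_value: float
    n: int
    converged: bool
    fit_scale: str = "original"  # or "log"
    sse: float = float("nan")
    error: str | None = None

    @property
    def param_dict(self) -> dict[str, float]:
        return dict(zip(self.form.param_names, np.asarray(self.params, float)))

    def predict(self, predictors):
        return predict(self.form, self.params, predictors)

    def to_dict(self) -> dict:
        return {
            "form_id": self.form.form_id,
            "family": self.form.family,
            "n_covariates": self.form.n_covariates,
            "scale": self.fit_scale,
            "params": [float(v) for v in np.asarray(self.params, float)],
            "param_names": list(self.form.param_names),
            "r2": float(self.r2),
            "f": float(self.f_value),
            "df1": int(self.df1),
            "df2": int(self.df2),
            "p": float(self.p_value),
            "n": int(self.n),
            "converged": bool(self.converged),
            "error": self.error,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def goodness_of_fit(observed, fitted, n_terms: int):
    """R², F, df and p for a fitted curve.

    R² = 1 − SSE/SStot; F = (R²/df1) / ((1 − R²)/df2) with df1 = n_terms
    (non-intercept parameters) and df2 = n − n_terms − 1; p is the upper
    tail of the F(df1, df2) distribution.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(fitted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and fitted must have equal length")
    n = y.size
    if n <= n_terms + 1:
        raise ValueError("need n > n_terms + 1 residual degrees of freedom")
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        raise UndefinedR2Error("response has zero variance")
    sse = float(np.sum((y - yhat) ** 2))
    r2 = 1.0 - sse / sstot
    df1, df2 = n_terms, n - n_terms - 1
    if r2 >= 1.0:
        f_value, p_value = float("inf"), 0.0
    else:
        f_value = max((r2 / df1) / ((1.0 - r2) / df2), 0.0)
        p_value = float(stats.f.sf(f_value, df1, df2))
    return r2, f_value, df1, df2, p_value


def fit_closed_form(form: ModelForm, x, y) -> FitResult:
    """OLS fit of a linearizable form on its transformed design.

    s_curve and growth regress ln y (``fit_scale='log'``); the reported
    R²/F/p are computed on that fitting scale, matching the convention of
    classic curve-estimation software.
    """
    y = np.asarray(y, dtype=float)
    design, log_response = linear_basis(form, x)
    n = y.size
    if design.shape[0] != n:
        raise ValueError("x and y lengths differ")
    if n <= form.n_params:
        raise ValueError("need n > number of parameters")
    if log_response:
        bad = np.nonzero(y <= 0)[0]
        if bad.size:
            raise DomainError(
                f"{form.family} needs y > 0 (log transform); offending "
                f"indices: {bad.tolist()[:10]}"
            )
        resp = np.log(y)
    else:
        resp = y
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise SingularDesignError(
            f"design for {form.form_id} is rank deficient ({rank} < {design.shape[1]})"
        )
    coef, *_ = np.linalg.lstsq(design, resp, rcond=None)
    fitted = design @ coef
    r2, f_value, df1, df2, p_value = goodness_of_fit(resp, fitted, form.n_terms)
    return FitResult(
        form=form, params=coef, r2=r2, f_value=f_value, df1=df1, df2=df2,
        p_value=p_value, n=n, converged=True,
        fit_scale="log" if log_response else "original",
        sse=float(np.sum((resp - fitted) ** 2)),
    )


def default_init(form: ModelForm, predictors, y) -> np.ndarray:
    """Data-driven starting point for nonlinear least squares.

    logistic: b1 = 1.05·max y, b3 = median x, b2 from the slope of the
    logit linearization ln(b1/y − 1) ~ x.  Linearizable forms start at
    their closed-form transform fit.  Multivariate forms start at the basic
    start with covariate coefficients 0.
    """
    X = _as_matrix(form, predictors)
    y = np.asarray(y, dtype=float)
    basic = ModelForm(form.family)
    x1 = X[:, 0]
    if form.family == "logistic":
        ymax = float(np.max(y))
        if ymax <= 0:
            raise DomainError("logistic initialization needs max y > 0")
        b1 = 1.05 * ymax
        b3 = float(np.median(x1))
        ratio = np.clip(b1 / np.clip(y, 1e-12, None) - 1.0, 1e-9, None)
        z = np.log(ratio)
        slope = float(np.polyfit(x1, z, 1)[0]) if x1.size > 1 else -0.1
        b2 = -slope if slope != 0 else 0.1
        base = np.array([b1, b2, b3])
    else:
        try:
            base = fit_closed_form(basic, x1, y).params
        except (DomainError, SingularDesignError):
            base = np.zeros(basic.n_params)
            base[0] = float(np.mean(y))
    return np.concatenate([base, np.zeros(form.n_covariates)])


def fit_nls(
    form: ModelForm,
    predictors,
    y,
    init="auto",
    tol: float = 1e-10,
    max_iter: int = 500,
    n_restarts: int = 3,
    restart_seed: int = 0,
) -> FitResult:
    """Trust-region nonlinear least squares on the original response scale.

    Works for every basic and multivariate form.  On non-convergence the
    best parameters so far are returned with ``converged=False`` after up
    to ``n_restarts`` seeded, jittered restarts (lowest SSE kept).
    """
    X = _as_matrix(form, predictors)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n <= form.n_params:
        raise ValueError("residual degrees of freedom <= 0")
    p0 = default_init(form, X, y) if isinstance(init, str) else np.asarray(init, float)
    if not np.all(np.isfinite(p0)):
        raise ValueError("initial parameters must be finite")

    def residuals(p):
        pred = predict(form, p, X, check_domain=False)
        pred = np.nan_to_num(pred, nan=_PENALTY, posinf=_PENALTY, neginf=-_PENALTY)
        return pred - y

    def run(p_start):
        return optimize.least_squares(
            residuals, p_start, method="trf",
            ftol=tol, xtol=tol, gtol=tol,
            max_nfev=max_iter * (form.n_params + 1),
        )

    sol = run(p0)
    rng = np.random.default_rng(restart_seed)
    tries = 0
    while sol.status <= 0 and tries < n_restarts:
        jitter = 1.0 + 0.2 * rng.standard_normal(p0.size)
        cand = run(p0 * jitter + 0.01 * rng.standard_normal(p0.size))
        if cand.cost < sol.cost:
            sol = cand
        tries += 1
    params = sol.x
    fitted = predict(form, params, X, check_domain=False)
    converged = bool(sol.status > 0)
    try:
        r2, f_value, df1, df2, p_value = goodness_of_fit(y, fitted, form.n_terms)
    except UndefinedR2Error:
        r2, f_value, p_value = 0.0, 0.0, 1.0
        df1, df2 = form.n_terms, n - form.n_terms - 1
        converged = False
    if form.family == "logistic" and (params[0] <= 0 or params[1] == 0):
        converged = False  # improper sigmoid: flag, do not hide
    return FitResult(
        form=form, params=params, r2=r2, f_value=f_value, df1=df1, df2=df2,
        p_value=p_value, n=n, converged=converged, fit_scale="original",
        sse=float(2 * sol.cost),
    )


def fit(form: ModelForm, predictors, y, prefer_closed_form: bool = True) -> FitResult:
    """Fit a form by the conventional route: OLS where linearizable
    (including multivariate extensions), NLS for logistic."""
    if prefer_closed_form and form.family in LINEARIZABLE:
        X = _as_matrix(form, predictors)
        return fit_closed_form(form, X, y)
    return fit_nls(form, predictors, y)
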