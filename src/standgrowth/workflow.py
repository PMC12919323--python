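"""Per-species analysis workflow.

For each species and relation (DBH → height, or age → DBH) the workflow
fits all candidate curve forms on the modelling partition, selects the
optimal form by R², extends it with the screened covariates into its
multivariate counterpart, and validates every retained model on the
hold-out partition with four accuracy indicators:

* mean error              ME   = mean(ŷ − y)
* mean relative error     MRE  = mean((ŷ − y)/y)
* root mean square error  RMSE = sqrt(Σ(ŷ − y)² / (n − p))
* coefficient of determination R² = 1 − SSE/SStot (hold-out mean in SStot)

where p is the number of independent variables of the fitted model (1 for
basic forms, 1 + number of covariates for multivariate ones).  Hold-out R²
may be negative and is not clamped; RMSE is nonnegative by construction.
Selection uses modelling-set R² only — validation metrics are reported,
never used to select.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import InventoryTable, SplitSpec, split_table
from .errors import SelectionError
from .growth_models import (
    FAMILIES,
    FitResult,
    ModelForm,
    fit,
    fit_nls,
)
from .screening import ScreeningResult, screen_and_select

#: relation -> (predictor column, response column)
RELATIONS = {
    "dbh_height": ("dbh_cm", "height_m"),
    "age_dbh": ("age_yr", "dbh_cm"),
}


@dataclass
class ValidationMetrics:
    me: float
    mre: float
    rmse: float
    r2: float
    n: int
    p: int
    mre_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "me": float(self.me),
            "mre": float(self.mre) if self.mre_defined else None,
            "rmse": float(self.rmse),
            "r2": float(self.r2),
            "n": int(self.n),
            "p": int(self.p),
        }


@dataclass
class SpeciesReport:
    species: str
    relation: str
    candidate_fits: list[FitResult]
    best: FitResult
    multivariate: FitResult | None = None
    validation: dict[str, ValidationMetrics] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)


def fit_candidates(
    table: InventoryTable,
    species: str,
    relation: str,
    forms=None,
) -> tuple[list[FitResult], dict[str, str]]:
    """Fit every requested basic form for one species.

    Individual form failures (domain errors, too few degrees of freedom)
    are recorded in the returned failure map, not fatal to the batch.
    """
    if relation not in RELATIONS:
        raise ValueError(f"unknown relation {relation!r}")
    sub = table.subset(species)
    if len(sub) == 0:
        raise ValueError(f"species {species!r} absent from the table")
    xcol, ycol = RELATIONS[relation]
    x, y = sub.column(xcol), sub.column(ycol)
    fits: list[FitResult] = []
    failures: dict[str, str] = {}
    for family in (forms or FAMILIES):
        form = ModelForm(family)
        try:
            fits.append(fit(form, x, y))
        except Exception as exc:  # per-form failure: record and continue
            failures[family] = f"{type(exc).__name__}: {exc}"
    return fits, failures


def select_best(fits, tie_tol: float = 0.0) -> FitResult:
    """Highest modelling-set R² among converged fits.

    Ties break by fewer parameters, then catalogue order.  ``tie_tol``
    optionally widens "tie" to R² values within that distance of the
    maximum (e.g. 0.0005, the resolution of a 3-decimal report table);
    the default is exact equality.
    """
    candidates = [f for f in fits if f.converged]
    if not candidates:
        raise SelectionError("no converged fits to select from")
    top = max(f.r2 for f in candidates)
    tied = [f for f in candidates if f.r2 >= top - tie_tol]
    return min(
        tied,
        key=lambda f: (-f.r2 if tie_tol == 0.0 else 0.0,
                       f.form.n_params, FAMILIES.index(f.form.family)),
    )


def extend_multivariate(best: FitResult | ModelForm, covariates) -> ModelForm:
    """The multivariate counterpart of a basic form, one slot per covariate."""
    form = best.form if isinstance(best, FitResult) else best
    if form.n_covariates:
        raise ValueError("form is already multivariate")
    k = len(list(covariates))
    if not 1 <= k <= 3:
        raise ValueError("1 to 3 covariates supported")
    return ModelForm(form.family, n_covariates=k)


def multivariate_init(best: FitResult, covariates) -> np.ndarray:
    """Start the extended fit at the basic fit with covariate coefficients 0."""
    k = len(list(covariates))
    return np.concatenate([np.asarray(best.params, float), np.zeros(k)])


def validate(
    fit_result: FitResult,
    holdout: InventoryTable,
    relation: str,
    covariates=None,
) -> ValidationMetrics:
    """Hold-out accuracy indicators for one fitted model."""
    xcol, ycol = RELATIONS[relation]
    covariates = list(covariates or [])
    if fit_result.form.n_covariates != len(covariates):
        raise ValueError("covariate list does not match the fitted form")
    X = np.column_stack(
        [holdout.column(xcol)] + [holdout.column(c) for c in covariates]
    ) if covariates else holdout.column(xcol)
    y = holdout.column(ycol)
    yhat = fit_result.predict(X)
    return validation_metrics(y, yhat, p=1 + len(covariates))


def validation_metrics(y, yhat, p: int) -> ValidationMetrics:
    """The four indicators from raw observed/predicted vectors."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    n = y.size
    if n == 0:
        raise ValueError("empty hold-out")
    if n <= p:
        raise ValueError("need n > p for the RMSE denominator")
    err = yhat - y
    me = float(np.mean(err))
    mre_defined = bool(np.all(y != 0))
    mre = float(np.mean(err / y)) if mre_defined else float("nan")
    rmse = float(np.sqrt(np.sum(err**2) / (n - p)))
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / sstot if sstot > 0 else float("nan")
    return ValidationMetrics(
        me=me, mre=mre, rmse=rmse, r2=r2, n=n, p=p, mre_defined=mre_defined
    )


def analyze_species(
    model_table: InventoryTable,
    holdout_table: InventoryTable,
    species: str,
    relation: str,
    covariates=None,
    forms=None,
) -> SpeciesReport:
    """Fit, select, extend and validate for one species × relation."""
    fits, failures = fit_candidates(model_table, species, relation, forms)
    best = select_best(fits)
    report = SpeciesReport(
        species=species, relation=relation,
        candidate_fits=fits, best=best, failures=failures,
    )
    holdout_sub = holdout_table.subset(species)
    p_basic = best.form.n_params
    if len(holdout_sub) > p_basic:
        report.validation["basic"] = validate(best, holdout_sub, relation)
    covariates = list(covariates or [])
    if covariates:
        sub = model_table.subset(species)
        xcol, ycol = RELATIONS[relation]
        X = np.column_stack(
            [sub.column(xcol)] + [sub.column(c) for c in covariates]
        )
        y = sub.column(ycol)
        mform = extend_multivariate(best, covariates)
        if len(sub) > mform.n_params:
            if mform.family == "logistic":
                mfit = fit_nls(mform, X, y, init=multivariate_init(best, covariates))
            else:
                mfit = fit(mform, X, y)
            report.multivariate = mfit
            if len(holdout_sub) > mform.n_params:
                report.validation["multivariate"] = validate(
                    mfit, holdout_sub, relation, covariates
                )
    return report


@dataclass
class WorkflowConfig:
    relations: tuple[str, ...] = ("dbh_height", "age_dbh")
    fractions: tuple[float, ...] = (0.7, 0.3)
    seed: int = 0
    stratify: bool = True
    k_covariates: int = 3
    screening_rule: str = "signed"
    vif_threshold: float = 5.0
    forms: tuple[str, ...] = FAMILIES


@dataclass
class WorkflowResult:
    screening: ScreeningResult
    reports: list[SpeciesReport]
    partitions: list[InventoryTable]


def run_workflow(table: InventoryTable, config: WorkflowConfig = None) -> WorkflowResult:
    """End-to-end analysis on a pooled inventory table.

    Splits 70/30 (seeded), screens covariates on the pooled modelling
    partition, then fits/selects/extends/validates per species × relation.
    """
    config = config or WorkflowConfig()
    model_t, holdout_t = split_table(
        table,
        SplitSpec(config.fractions, config.seed, config.stratify),
    )[:2]
    screening = screen_and_select(
        model_t, response="dbh", k=config.k_covariates,
        rule=config.screening_rule, vif_threshold=config.vif_threshold,
    )
    reports = []
    for relation in config.relations:
        for species in table.species:
            try:
                reports.append(
                    analyze_species(
                        model_t, holdout_t, species, relation,
                        covariates=screening.selected, forms=config.forms,
                    )
                )
            except SelectionError:
                continue
    return WorkflowResult(screening=screening, reports=reports,
                          partitions=[model_t, holdout_t])


def build_report(reports, layout: str = "basic") -> pd.DataFrame:
    """Tabulate species reports in one of the published table layouts.

    ``basic``: one row per species × candidate form with R², F, df, p and
    coefficients.  ``multivariate``: the extended fit per species.
    ``validation``: ME / MRE / RMSE (and R²) per species × model.
    Numeric cells are rounded to 3 decimals; full precision lives in the
    FitResult objects.
    """
    if not reports:
        raise ValueError("no reports to tabulate")
    rows = []
    if layout == "basic":
        for rep in reports:
            for f in rep.candidate_fits:
                row = {
                    "species": rep.species, "relation": rep.relation,
                    "equation": f.form.family, "r2": f.r2, "f_value": f.f_value,
                    "df1": f.df1, "df2": f.df2, "p_value": f.p_value,
                }
                for name, val in f.param_dict.items():
                    row[name] = val
                rows.append(row)
    elif layout == "multivariate":
        for rep in reports:
            if rep.multivariate is None:
                continue
            f = rep.multivariate
            row = {
                "species": rep.species, "relation": rep.relation,
                "equation": f.form.form_id, "r2": f.r2,
            }
            for name, val in f.param_dict.items():
                row[name] = val
            rows.append(row)
    elif layout == "validation":
        for rep in reports:
            for kind, vm in rep.validation.items():
                rows.append({
                    "species": rep.species, "relation": rep.relation,
                    "model": kind, "me": vm.me, "mre": vm.mre,
                    "rmse": vm.rmse, "r2": vm.r2,
                })
    else:
        raise ValueError(f"unknown layout {layout!r}")
    df = pd.DataFrame(rows)
    return df.round(3)
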