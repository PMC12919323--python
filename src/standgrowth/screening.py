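"""Covariate screening by correlation with DBH, and VIF diagnostics.

The screening step ranks per-plot environmental covariates by their Pearson
correlation with diameter at breast height, keeps the top three, and checks
the retained set for multicollinearity with variance inflation factors
(threshold 5).  Two ranking rules are provided: ``signed`` (r descending,
the default) and ``absolute`` (|r| descending); ties break by catalogue
order, i.e. the order covariates appear in the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import InventoryTable
from .errors import CollinearityError, ScreeningError

VIF_THRESHOLD_DEFAULT = 5.0

_RESPONSE_ALIASES = {"dbh": "dbh_cm", "height": "height_m", "age": "age_yr"}


@dataclass
class ScreeningResult:
    correlations: list[tuple[str, float]]
    selected: list[str]
    vif: dict[str, float]
    vif_threshold: float = VIF_THRESHOLD_DEFAULT
    constant: list[str] = field(default_factory=list)

    @property
    def flagged(self) -> list[str]:
        """Covariates whose VIF exceeds the threshold."""
        return [k for k, v in self.vif.items() if v > self.vif_threshold]

    def to_dict(self) -> dict:
        return {
            "correlations": [[n, float(r)] for n, r in self.correlations],
            "selected": list(self.selected),
            "vif": {k: float(v) for k, v in self.vif.items()},
            "vif_threshold": self.vif_threshold,
            "constant": list(self.constant),
        }


def pearson_r(x, y) -> float:
    """Plain Pearson product-moment correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0:
        return float("nan")
    return float(np.clip(np.sum(xc * yc) / denom, -1.0, 1.0))


def screen_covariates(table: InventoryTable, response: str = "dbh"):
    """Correlate every covariate with the response, in catalogue order.

    Returns
    -------
    (list of (name, r), list of constant covariate names)
        Constant covariates have undefined r and are excluded from the
        ranked list.
    """
    if len(table) < 3:
        raise ScreeningError("need at least 3 records to screen")
    col = _RESPONSE_ALIASES.get(response, response)
    y = table.column(col)
    out, constant = [], []
    for name in table.covariates:
        x = table.column(name)
        if np.ptp(x) == 0:
            constant.append(name)
            continue
        out.append((name, pearson_r(x, y)))
    if not out:
        raise ScreeningError("all covariates are constant")
    return out, constant


def select_top(screened, k: int = 3, rule: str = "signed") -> list[str]:
    """The k strongest covariates under the ranking rule.

    ``signed`` sorts by r descending; ``absolute`` by |r| descending.
    The sort is stable, so ties keep the catalogue order of the input.
    """
    if rule not in ("signed", "absolute"):
        raise ValueError(f"unknown rule {rule!r}")
    if k > len(screened):
        raise ValueError(f"k={k} exceeds the {len(screened)} ranked covariates")
    key = (lambda t: -t[1]) if rule == "signed" else (lambda t: -abs(t[1]))
    ranked = sorted(screened, key=key)
    return [name for name, _ in ranked[:k]]


def vif(table: InventoryTable, covariates) -> dict[str, float]:
    """Variance inflation factors for a covariate set.

    VIF_j = 1 / (1 − R²_j) with R²_j from the OLS regression of covariate j
    on the others plus an intercept.  Exact collinearity raises
    :class:`CollinearityError` naming the offending covariate(s).
    """
    covariates = list(covariates)
    if len(table) < len(covariates) + 2:
        raise ValueError("need at least |covariates| + 2 records")
    Z = np.column_stack([table.column(c) for c in covariates])
    n = Z.shape[0]
    out: dict[str, float] = {}
    offenders: list[str] = []
    for j, name in enumerate(covariates):
        yj = Z[:, j]
        others = np.delete(Z, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ coef
        sstot = np.sum((yj - yj.mean()) ** 2)
        if sstot == 0:
            offenders.append(name)
            continue
        r2_j = 1.0 - np.sum(resid**2) / sstot
        if r2_j > 1.0 - 1e-10:
            offenders.append(name)
            continue
        out[name] = 1.0 / (1.0 - r2_j)
    if offenders:
        raise CollinearityError(offenders)
    return out


def screen_and_select(
    table: InventoryTable,
    response: str = "dbh",
    k: int = 3,
    rule: str = "signed",
    vif_threshold: float = VIF_THRESHOLD_DEFAULT,
) -> ScreeningResult:
    """Full screening pass: correlations, top-k selection, VIF check."""
    screened, constant = screen_covariates(table, response)
    selected = select_top(screened, k=k, rule=rule)
    vifs = vif(table, selected)
    return ScreeningResult(
        correlations=screened, selected=selected, vif=vifs,
        vif_threshold=vif_threshold, constant=constant,
    )
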