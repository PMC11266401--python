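"""Two-part regression, recycled predictions, and KMSA cumulative estimates.

The per-period mean of a zero-inflated outcome is decomposed as
P(any use) x E[amount | use], with a logistic model for the first part and
a log-link GLM (gamma for costs, negative binomial for counts) for the
second, fitted separately within each cohort and period on cells observed
to completion (including death-within cells, whose truncated accrual is
real). Recycled predictions standardise each fit over the cohort's full
baseline covariate distribution; the Kaplan-Meier sample average (KMSA)
estimator weights each period's standardised mean by the probability of
being alive at the period start and sums the weighted means up to the
reporting horizon. Subtracting the comparator estimate from the case
estimate at each horizon yields the attributable (incremental) quantity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .codes import COMORBIDITY_CATEGORIES
from .cohort import completed_age
from .panel import COUNT_COMPONENTS, FIT_STATUSES, PERIOD_SCHEME, PeriodScheme
from .survival import KMCurve, survival_at

logger = logging.getLogger(__name__)

HORIZONS = (365, 730, 1095)

#: ceiling on |coefficient| beyond which a logistic fit is treated as separated
_SEPARATION_BOUND = 15.0


class ContractError(ValueError):
    """Inputs violate a cross-module contract (mismatched spec/columns)."""


def design_matrix(cohort: pd.DataFrame, persons: pd.DataFrame,
                  profiles: pd.DataFrame, age_bands: bool = False) -> pd.DataFrame:
    """Covariate matrix indexed by patient_id: age, sex, region, comorbidity.

    Age enters continuously (in years at index) by default; ``age_bands``
    switches to decade-band indicators. Region uses indicator contrasts
    against the first region in sorted order.
    """
    p = persons.set_index("patient_id")
    X = pd.DataFrame(index=pd.Index(cohort["patient_id"], name="patient_id"))
    X["const"] = 1.0
    birth = cohort["patient_id"].map(p["birth_date"]).to_numpy()
    age = (pd.to_datetime(cohort["index_date"].to_numpy())
           - pd.to_datetime(birth)).days / 365.25
    if age_bands:
        yrs = completed_age(birth, cohort["index_date"].to_numpy())
        for lo in (30, 40, 50, 60, 70, 80):
            hi = lo + 9 if lo < 80 else 200
            X[f"age_{lo}"] = ((yrs >= lo) & (yrs <= hi)).astype(float)
    else:
        X["age"] = np.asarray(age)
    X["male"] = (cohort["patient_id"].map(p["sex"]) == "male").to_numpy(float)
    regions = sorted(p["region"].dropna().unique())
    for r in regions[1:]:
        X[f"region_{r}"] = (cohort["patient_id"].map(p["region"]) == r).to_numpy(float)
    prof = profiles.set_index("patient_id")
    for cat in COMORBIDITY_CATEGORIES:
        X[f"cm_{cat}"] = cohort["patient_id"].map(prof[cat]).fillna(0).to_numpy(float)
    return X


@dataclass
class TwoPartFit:
    """Fitted two-part model for one cohort x component x period cell."""

    role: str
    component: str
    period: int
    columns: tuple[str, ...]
    part1_params: np.ndarray | None = None   # logistic coefficients
    part1_prob: float | None = None          # degenerate/intercept-only P(use)
    part2_params: np.ndarray | None = None   # log-link GLM coefficients
    part2_mean: float | None = None          # intercept-only conditional mean
    family: str = "gamma"
    n_fit: int = 0
    n_pos: int = 0
    structural_zero: bool = False
    notes: list[str] = field(default_factory=list)


def _part2_family(component: str, family: str | None, nb_alpha: float):
    if family is None or family == "auto":
        family = "negbin" if component in COUNT_COMPONENTS else "gamma"
    if family == "gamma":
        return "gamma", sm.families.Gamma(link=sm.families.links.Log())
    if family == "negbin":
        return "negbin", sm.families.NegativeBinomial(
            alpha=nb_alpha, link=sm.families.links.Log())
    raise ValueError(f"unknown part-2 family {family!r}")


def fit_two_part_arrays(y: np.ndarray, X: np.ndarray, columns: tuple[str, ...],
                        role: str, component: str, period: int,
                        family: str | None = None,
                        nb_alpha: float = 1.0) -> TwoPartFit:
    """Core fitting routine on plain arrays (used directly by the bootstrap)."""
    fit = TwoPartFit(role, component, period, columns, n_fit=len(y))
    fam_name, fam = _part2_family(component, family, nb_alpha)
    fit.family = fam_name
    pos = y > 0
    fit.n_pos = int(pos.sum())

    if fit.n_fit == 0 or fit.n_pos == 0:
        fit.structural_zero = True
        fit.part1_prob, fit.part2_mean = 0.0, 0.0
        return fit

    k = X.shape[1]
    if pos.all():
        fit.part1_prob = 1.0
    elif k == 1:
        fit.part1_prob = float(pos.mean())
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(pos.astype(float), X, family=sm.families.Binomial()).fit(
                    maxiter=100, tol=1e-10)
            if (not np.all(np.isfinite(res.params))
                    or np.max(np.abs(res.params[1:] if k > 1 else res.params))
                    > _SEPARATION_BOUND):
                raise ValueError("separation")
            fit.part1_params = np.asarray(res.params)
        except Exception:
            fit.part1_prob = float(pos.mean())
            fit.notes.append("part1 fell back to intercept-only (separation)")
            logger.warning("two-part %s/%s p%d: part1 separation fallback",
                           role, component, period)

    yp, Xp = y[pos], X[pos]
    if k == 1 or fit.n_pos < k + 1:
        fit.part2_mean = float(yp.mean())
        if k > 1:
            fit.notes.append("part2 fell back to intercept-only (too few positives)")
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res2 = sm.GLM(yp, Xp, family=fam).fit(maxiter=200, tol=1e-10)
            if not np.all(np.isfinite(res2.params)):
                raise ValueError("non-finite")
            fit.part2_params = np.asarray(res2.params)
        except Exception:
            fit.part2_mean = float(yp.mean())
            fit.notes.append("part2 fell back to intercept-only (no convergence)")
            logger.warning("two-part %s/%s p%d: part2 fallback", role, component, period)
    return fit


def fit_two_part(panel: pd.DataFrame, X: pd.DataFrame, role: str,
                 component: str, period: int, family: str | None = None,
                 nb_alpha: float = 1.0) -> TwoPartFit:
    """Fit one cell on panel rows observed to completion (incl. deaths)."""
    rows = panel[(panel["role"] == role) & (panel["period"] == period)
                 & panel["status"].isin(FIT_STATUSES)]
    Xr = X.loc[X.index.intersection(rows["patient_id"])]
    sub = rows.set_index("patient_id").loc[Xr.index]
    return fit_two_part_arrays(
        sub[component].to_numpy(dtype=float), Xr.to_numpy(dtype=float),
        tuple(X.columns), role, component, period, family, nb_alpha,
    )


def recycled_predict(fit: TwoPartFit, X: pd.DataFrame | np.ndarray) -> float:
    """Standardised per-period mean over a reference covariate distribution.

    mu = average over rows of P(use | x) * E[amount | use, x].
    """
    if isinstance(X, pd.DataFrame):
        if tuple(X.columns) != tuple(fit.columns):
            raise ContractError(
                f"covariate columns {tuple(X.columns)} != fit spec {fit.columns}")
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.shape[1] != len(fit.columns):
            raise ContractError("covariate width mismatch with fit spec")
    if fit.structural_zero:
        return 0.0
    p = (np.full(len(Xa), fit.part1_prob) if fit.part1_params is None
         else expit(Xa @ fit.part1_params))
    m = (np.full(len(Xa), fit.part2_mean) if fit.part2_params is None
         else np.exp(Xa @ fit.part2_params))
    return float(np.mean(p * m))


@dataclass(frozen=True)
class KMSAEstimate:
    """Survival-weighted cumulative estimate for one cohort and component."""

    role: str
    component: str
    period_means: dict[int, float]      # recycled predictions mu_p
    weights: dict[int, float]           # S(s_p)
    cumulative: dict[int, float]        # horizon (days) -> estimate


def kmsa_cumulative(fits: dict[int, TwoPartFit], curve: KMCurve,
                    X: pd.DataFrame | np.ndarray,
                    scheme: PeriodScheme = PERIOD_SCHEME,
                    horizons: tuple[int, ...] = HORIZONS) -> KMSAEstimate:
    """Sum of S(s_p) x mu_p over periods starting before each horizon."""
    max_h = max(horizons)
    needed = [p + 1 for p, (s, _e) in enumerate(scheme.bounds) if s < max_h]
    missing = [p for p in needed if p not in fits]
    if missing:
        raise ContractError(f"missing period fits: {missing}")
    roles = {fits[p].role for p in needed}
    comps = {fits[p].component for p in needed}
    if len(roles) > 1 or len(comps) > 1:
        raise ContractError("fits mix cohorts or components")
    mus, weights = {}, {}
    for p in needed:
        s = scheme.bounds[p - 1][0]
        weights[p] = float(survival_at(curve, s))
        mus[p] = recycled_predict(fits[p], X)
    cumulative = {
        h: float(sum(weights[p] * mus[p]
                     for p in needed if scheme.bounds[p - 1][0] < h))
        for h in horizons
    }
    return KMSAEstimate(roles.pop(), comps.pop(), mus, weights, cumulative)


def incremental_cost(case_est, comp_est) -> dict[int, float]:
    """Attributable quantity per horizon: case minus matched comparator."""
    if isinstance(case_est, KMSAEstimate) and isinstance(comp_est, KMSAEstimate):
        if case_est.component != comp_est.component:
            raise ContractError("component mismatch between cohort estimates")
        a, b = case_est.cumulative, comp_est.cumulative
    else:
        a = case_est.cumulative if isinstance(case_est, KMSAEstimate) else dict(case_est)
        b = comp_est.cumulative if isinstance(comp_est, KMSAEstimate) else dict(comp_est)
    if set(a) != set(b):
        raise ContractError("horizon mismatch between cohort estimates")
    return {h: a[h] - b[h] for h in sorted(a)}
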