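"""Nonparametric bootstrap over the full KMSA estimation pipeline.

Patients are resampled with replacement within each cohort at the original
cohort size (matched sets are deliberately broken; a set-preserving mode
resamples case patients and carries their whole matched set). Every
replicate refits the Kaplan-Meier weights and all two-part models, then
recomputes recycled predictions, KMSA cumulatives, and incremental
differences, so the interval reflects the whole estimation procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import FIT_STATUSES, PERIOD_SCHEME, PeriodScheme
from .survival import km_weights
from .twopart import HORIZONS, fit_two_part_arrays, recycled_predict

__all__ = ["BootstrapSummary", "bootstrap_kmsa"]


@dataclass(frozen=True)
class BootstrapSummary:
    estimand: str           # "<role or incremental>/<component>/<horizon>"
    B: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float


class _CohortArrays:
    """Panel, covariates and survival data flattened to arrays per cohort."""

    def __init__(self, panel, X, surv, role, components, scheme):
        sub = panel[panel["role"] == role]
        pids = X.index.to_numpy()
        pid_pos = {pid: i for i, pid in enumerate(pids)}
        n, P = len(pids), scheme.n_periods
        self.n, self.P = n, P
        self.X = X.to_numpy(dtype=float)
        self.columns = tuple(X.columns)
        self.role = role
        self.y = {c: np.zeros((n, P)) for c in components}
        self.fit_mask = np.zeros((n, P), dtype=bool)
        rows = sub["patient_id"].map(pid_pos).to_numpy()
        per = sub["period"].to_numpy() - 1
        ok = sub["status"].isin(FIT_STATUSES).to_numpy()
        self.fit_mask[rows[ok], per[ok]] = True
        for c in components:
            self.y[c][rows, per] = sub[c].to_numpy(dtype=float)
        s = surv.set_index("patient_id").loc[pids]
        self.time = s["time"].to_numpy(dtype=float)
        self.event = s["event"].to_numpy(dtype=int)


def _replicate_estimate(arr: _CohortArrays, idx: np.ndarray, scheme, components,
                        horizons, covariates: bool, family_by: dict):
    weights = km_weights(arr.time[idx], arr.event[idx], scheme.starts.astype(float))
    out = {}
    Xb = arr.X[idx]
    for c in components:
        cum = {h: 0.0 for h in horizons}
        for p in range(arr.P):
            s = scheme.bounds[p][0]
            mask = arr.fit_mask[idx, p]
            y = arr.y[c][idx, p][mask]
            if covariates:
                fit = fit_two_part_arrays(
                    y, Xb[mask], arr.columns, arr.role, c, p + 1,
                    family=family_by.get(c))
                mu = recycled_predict(fit, Xb)
            else:
                mu = float(y.mean()) if len(y) else 0.0
            for h in horizons:
                if s < h:
                    cum[h] += weights[p] * mu
        out[c] = cum
    return out


def bootstrap_kmsa(panel: pd.DataFrame, X_by_role: dict[str, pd.DataFrame],
                   surv: pd.DataFrame, components: tuple[str, ...],
                   B: int = 1000, seed: int = 0,
                   scheme: PeriodScheme = PERIOD_SCHEME,
                   horizons: tuple[int, ...] = HORIZONS,
                   covariates: bool = True,
                   family_by: dict | None = None,
                   preserve_sets: bool = False,
                   cohort: pd.DataFrame | None = None):
    """Bootstrap the KMSA cumulatives and incremental differences.

    Parameters
    ----------
    X_by_role : dict role -> design matrix indexed by patient_id (full cohort
        membership; also defines the resampling frame).
    covariates : when False, use the closed-form intercept-only two-part fit
        (period mean over fit-eligible cells) — the exact same estimator with
        an intercept-only covariate specification.
    preserve_sets : resample matched sets (by case patient) instead of
        breaking them; requires ``cohort`` with matched_set_id.

    Returns (summaries: list[BootstrapSummary], replicates: DataFrame).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    family_by = family_by or {}
    roles = list(X_by_role)
    arrays = {r: _CohortArrays(panel, X_by_role[r], surv, r, components, scheme)
              for r in roles}

    set_members = None
    if preserve_sets:
        if cohort is None:
            raise ValueError("preserve_sets requires the cohort assignment table")
        set_members = {
            r: cohort[cohort["role"] == r].groupby("matched_set_id")["patient_id"]
            .apply(list).to_dict()
            for r in roles
        }

    records = []
    for b in range(B):
        rep = {}
        for r in roles:
            arr = arrays[r]
            if preserve_sets:
                sets = list(set_members[r])
                pick = rng.integers(0, len(sets), size=len(sets))
                pid_pos = {pid: i for i, pid in enumerate(X_by_role[r].index)}
                idx = np.array([pid_pos[pid] for s in pick
                                for pid in set_members[r][sets[s]]])
            else:
                idx = rng.integers(0, arr.n, size=arr.n)
            rep[r] = _replicate_estimate(arr, idx, scheme, components,
                                         horizons, covariates, family_by)
        for c in components:
            for h in horizons:
                for r in roles:
                    records.append((b, r, c, h, rep[r][c][h]))
                if {"case", "comparator"} <= set(roles):
                    records.append((b, "incremental", c, h,
                                    rep["case"][c][h] - rep["comparator"][c][h]))

    reps = pd.DataFrame(records, columns=["b", "estimand", "component",
                                          "horizon", "value"])
    summaries = []
    for (est, c, h), g in reps.groupby(["estimand", "component", "horizon"]):
        v = g["value"].to_numpy()
        summaries.append(BootstrapSummary(
            estimand=f"{est}/{c}/{h}", B=B,
            mean=float(v.mean()), sd=float(v.std(ddof=1)),
            ci_low=float(np.percentile(v, 2.5)),
            ci_high=float(np.percentile(v, 97.5)),
        ))
    return summaries, reps
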