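"""Observation-period partition and patient x period HRU/cost aggregation.

Follow-up is partitioned into seven modelling periods — four quarters
(91/91/91/92 d), two half-years, one full year — so that year boundaries
land exactly at 365/730/1095 days. Mortality is stable after the first
year, so quarters are collapsed beyond it; a 12-quarter scheme is available
for sensitivity analyses. Each patient x period cell carries an observation
status, per-setting use counts, and costs; cells with only partial
administrative observation (the data end inside the period) retain their
observed costs but are excluded from model fitting downstream, while
death-within cells count as complete (death legitimately ends accrual).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COUNT_COMPONENTS = ("visits_outpatient", "visits_emergency", "admissions",
                    "hospital_days")
COST_COMPONENTS = ("cost_total", "cost_outpatient", "cost_inpatient",
                   "cost_emergency", "cost_medication", "cost_nonmedication")
COMPONENTS = COUNT_COMPONENTS + COST_COMPONENTS

STATUSES = ("complete", "died_within", "censored_within", "not_entered")
FIT_STATUSES = ("complete", "died_within")


@dataclass(frozen=True)
class PeriodScheme:
    """Contiguous half-open periods [start, end) in days from index."""

    bounds: tuple[tuple[int, int], ...]

    def __post_init__(self):
        for (s0, e0), (s1, _e1) in zip(self.bounds, self.bounds[1:]):
            if e0 != s1 or e0 <= s0:
                raise ValueError("periods must be contiguous and non-empty")
        if self.bounds[0][0] != 0:
            raise ValueError("first period must start at day 0")

    @property
    def n_periods(self) -> int:
        return len(self.bounds)

    @property
    def starts(self) -> np.ndarray:
        return np.array([s for s, _ in self.bounds])

    @property
    def horizon(self) -> int:
        return self.bounds[-1][1]

    def year_of(self, period: int) -> int:
        """Follow-up year (1-based) a period ends in."""
        e = self.bounds[period - 1][1]
        return int(np.ceil(e / 365))


PERIOD_SCHEME = PeriodScheme(
    ((0, 91), (91, 182), (182, 273), (273, 365),
     (365, 548), (548, 730), (730, 1095))
)
QUARTERLY_SCHEME = PeriodScheme(tuple(
    (s, e) for s, e in zip(
        [0, 91, 182, 273, 365, 456, 547, 638, 730, 821, 912, 1003],
        [91, 182, 273, 365, 456, 547, 638, 730, 821, 912, 1003, 1095],
    )
))

PRE_INDEX_WINDOW = (-365, -1)  # closed


def _aggregate_claims(sub: pd.DataFrame, key_cols: list[str]) -> pd.DataFrame:
    """Sum claims rows into component columns grouped by key_cols."""
    total = sub["medication_cost"] + sub["non_medication_cost"]
    tmp = pd.DataFrame({
        **{k: sub[k].to_numpy() for k in key_cols},
        "visits_outpatient": (sub["setting"] == "outpatient").astype(int),
        "visits_emergency": (sub["setting"] == "emergency").astype(int),
        "admissions": (sub["setting"] == "inpatient").astype(int),
        "hospital_days": sub["inpatient_days"].to_numpy(),
        "cost_total": total.to_numpy(),
        "cost_outpatient": np.where(sub["setting"] == "outpatient", total, 0),
        "cost_inpatient": np.where(sub["setting"] == "inpatient", total, 0),
        "cost_emergency": np.where(sub["setting"] == "emergency", total, 0),
        "cost_medication": sub["medication_cost"].to_numpy(),
        "cost_nonmedication": sub["non_medication_cost"].to_numpy(),
    })
    return tmp.groupby(key_cols, sort=False).sum().reset_index()


def build_panel(cohort: pd.DataFrame, claims: pd.DataFrame,
                persons: pd.DataFrame,
                scheme: PeriodScheme = PERIOD_SCHEME) -> pd.DataFrame:
    """Patient x period cells with observation status and aggregated outcomes.

    A patient enters a period if alive and enrolled at its start day; the
    status is ``died_within`` when the (observed) death falls inside the
    period, ``censored_within`` when the data end cuts the period while the
    patient is alive, else ``complete``. Claims outside the pre-index year
    or the follow-up horizon are ignored (counted in the log).
    """
    p = persons.set_index("patient_id")
    idx = pd.to_datetime(cohort["index_date"])
    death = pd.to_datetime(cohort["patient_id"].map(p["death_date"]))
    end = pd.to_datetime(cohort["patient_id"].map(p["enroll_end"]))
    death_day = (death - idx).dt.days.to_numpy(dtype=float)
    death_day = np.where(np.isnan(death_day), np.inf, death_day)
    cens_day = (end - idx).dt.days.to_numpy(dtype=float)

    n = len(cohort)
    pieces = []
    for pnum, (s, e) in enumerate(scheme.bounds, start=1):
        entered = np.minimum(death_day, cens_day + 1) > s
        died = entered & (death_day < e) & (death_day <= cens_day)
        complete = entered & ~died & (cens_day + 1 >= e)
        status = np.where(~entered, "not_entered",
                          np.where(died, "died_within",
                                   np.where(complete, "complete", "censored_within")))
        pieces.append(pd.DataFrame({
            "patient_id": cohort["patient_id"].to_numpy(),
            "role": cohort["role"].to_numpy() if "role" in cohort else "case",
            "period": pnum, "status": status,
        }))
    panel = pd.concat(pieces, ignore_index=True)

    # aggregate claims into periods
    sub = claims[claims["patient_id"].isin(set(cohort["patient_id"]))].copy()
    idx_map = dict(zip(cohort["patient_id"], idx))
    day = (sub["service_date"] - sub["patient_id"].map(idx_map)).dt.days
    in_window = (day >= PRE_INDEX_WINDOW[0]) & (day < scheme.horizon)
    n_ignored = int((~in_window).sum())
    if n_ignored:
        logger.info("build_panel: %d claims outside [-365, %d) ignored",
                    n_ignored, scheme.horizon)
    sub, day = sub[in_window], day[in_window]
    follow = day >= 0
    sub = sub[follow].copy()
    day = day[follow]
    starts = scheme.starts
    sub["period"] = np.searchsorted(starts, day.to_numpy(), side="right")

    agg = _aggregate_claims(sub, ["patient_id", "period"])
    panel = panel.merge(agg, on=["patient_id", "period"], how="left")
    for c in COMPONENTS:
        panel[c] = panel[c].astype(float).fillna(0.0)
        panel.loc[panel["status"] == "not_entered", c] = 0.0
        panel[f"any_{c}"] = (panel[c] > 0).astype(int)
    return panel.sort_values(["patient_id", "period"],
                             kind="mergesort").reset_index(drop=True)


def crude_annual_summary(panel: pd.DataFrame,
                         scheme: PeriodScheme = PERIOD_SCHEME,
                         denominator: str = "entering") -> pd.DataFrame:
    """Unadjusted per-cohort annual means of HRU and costs.

    ``denominator='entering'`` averages over patients alive and enrolled at
    the year start (the default); ``'all'`` averages over the full cohort.
    Years with no entering patients are omitted.
    """
    years = {p + 1: scheme.year_of(p + 1) for p in range(scheme.n_periods)}
    panel = panel.copy()
    panel["year"] = panel["period"].map(years)
    first_period = {y: min(p for p, yy in years.items() if yy == y)
                    for y in set(years.values())}
    rows = []
    for role, g in panel.groupby("role"):
        for year in sorted(set(years.values())):
            gy = g[g["year"] == year]
            enters = gy[(gy["period"] == first_period[year])
                        & (gy["status"] != "not_entered")]["patient_id"]
            denom = enters if denominator == "entering" else g["patient_id"].unique()
            if len(denom) == 0:
                continue
            totals = gy[gy["patient_id"].isin(set(denom))].groupby("patient_id")[
                list(COMPONENTS)].sum().reindex(denom).fillna(0.0)
            row = {"role": role, "year": year, "n": len(denom)}
            row.update(totals.mean().to_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def pre_index_summary(cohort: pd.DataFrame, claims: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort mean HRU/costs over the 365 days before index (closed window).

    Claims on the index date itself belong to follow-up, not baseline.
    """
    sub = claims[claims["patient_id"].isin(set(cohort["patient_id"]))].copy()
    idx_map = dict(zip(cohort["patient_id"], pd.to_datetime(cohort["index_date"])))
    day = (sub["service_date"] - sub["patient_id"].map(idx_map)).dt.days
    lo, hi = PRE_INDEX_WINDOW
    sub = sub[(day >= lo) & (day <= hi)]
    agg = _aggregate_claims(sub, ["patient_id"]) if len(sub) else pd.DataFrame(
        columns=["patient_id", *COMPONENTS])
    rows = []
    for role, g in cohort.groupby("role"):
        totals = agg.set_index("patient_id").reindex(g["patient_id"])
        totals = totals[list(COMPONENTS)].astype(float).fillna(0.0)
        row = {"role": role, "n": len(g)}
        row.update(totals.mean().to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
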