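"""Product-limit survival estimation supplying the KMSA period weights.

Follow-up runs from the index/reference date to death or the administrative
data end, whichever is first; there is no loss to follow-up (universal
coverage), so censoring is purely administrative. The survival function is
defined as S(t) = P(T > t) and evaluated at period starts, where it serves
as the probability of being alive at the start of each observation period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KMCurve:
    """Step-function product-limit estimate with risk-set bookkeeping."""

    event_times: np.ndarray   # strictly increasing death times
    survival: np.ndarray      # S just after each event time (non-increasing)
    n_risk: np.ndarray
    n_event: np.ndarray
    max_observed: float       # last observed time (event or censoring)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times, "survival": self.survival,
            "n_risk": self.n_risk, "n_event": self.n_event,
        })


def survival_inputs(cohort: pd.DataFrame, persons: pd.DataFrame,
                    data_end=None) -> pd.DataFrame:
    """Per-patient (time, event) from index to min(death, data end).

    Ties between a death date and the data end count as observed deaths
    (deaths-first convention).
    """
    p = persons.set_index("patient_id")
    idx = pd.to_datetime(cohort["index_date"])
    death = pd.to_datetime(cohort["patient_id"].map(p["death_date"]))
    end = pd.to_datetime(data_end) if data_end is not None else pd.to_datetime(
        cohort["patient_id"].map(p["enroll_end"])
    )
    death_day = (death - idx).dt.days
    cens_day = (end - idx).dt.days
    event = death_day.notna() & (death_day <= cens_day)
    time = np.where(event, death_day, cens_day)
    return pd.DataFrame({
        "patient_id": cohort["patient_id"].to_numpy(),
        "time": time.astype(float),
        "event": event.astype(int).to_numpy(),
    })


def km_fit(inputs: pd.DataFrame) -> KMCurve:
    """Standard Kaplan-Meier product-limit fit (deaths before censorings at ties)."""
    if len(inputs) == 0:
        raise ValueError("need at least one subject")
    t = np.asarray(inputs["time"], dtype=float)
    e = np.asarray(inputs["event"], dtype=int)
    if np.any(t < 0):
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    return KMCurve(
        event_times=ev.index.to_numpy(dtype=float),
        survival=kmf.survival_function_at_times(ev.index).to_numpy(),
        n_risk=ev["at_risk"].to_numpy(),
        n_event=ev["observed"].to_numpy(),
        max_observed=float(t.max()),
    )


def km_weights(durations: np.ndarray, events: np.ndarray,
               times: np.ndarray) -> np.ndarray:
    """S(t) at the requested times from raw arrays (fast path, no frames).

    Same product-limit estimate as :func:`km_fit`; used in tight loops
    (bootstrap replicates) where constructing fitter objects dominates.
    """
    order = np.argsort(durations, kind="mergesort")
    t = durations[order]
    e = events[order]
    n = len(t)
    # distinct death times with counts, risk set just before each
    death_t = t[e == 1]
    if death_t.size == 0:
        return np.ones(len(times))
    uniq, counts = np.unique(death_t, return_counts=True)
    at_risk = n - np.searchsorted(t, uniq, side="left")
    s = np.cumprod(1.0 - counts / at_risk)
    idx = np.searchsorted(uniq, np.asarray(times, dtype=float), side="right")
    out = np.ones(len(idx))
    pos = idx > 0
    out[pos] = s[idx[pos] - 1]
    return out


def survival_at(curve: KMCurve, t_days) -> np.ndarray | float:
    """Evaluate the right-continuous step function S(t) = P(T > t)."""
    t = np.asarray(t_days, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_days must be >= 0")
    if np.any(t > curve.max_observed):
        logger.warning(
            "survival_at: time beyond last observed (%.0f d); carrying last value",
            curve.max_observed,
        )
    scalar = t.shape == ()
    t1 = np.atleast_1d(t)
    idx = np.searchsorted(curve.event_times, t1, side="right")
    out = np.ones(len(t1))
    pos = idx > 0
    out[pos] = curve.survival[idx[pos] - 1]
    return float(out[0]) if scalar else out
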