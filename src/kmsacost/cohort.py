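"""Case identification, exclusions, and 1:10 exact matching.

Implements the claims-based definition of newly diagnosed AL amyloidosis:
one inpatient or two outpatient claims (any diagnosis position, the
outpatient pair at least 30 days apart) with a qualifying code, a biopsy
procedure claim within -12/+6 months of the index date, and exclusion of
patients with the legacy 2015 ICD-9 amyloidosis code, a later switch to a
non-AL amyloidosis code, or a confirmed non-AL registry record. Comparators
are drawn uniformly without replacement from an amyloidosis-free pool,
matched exactly on sex, residential region, and completed age at the case's
index date.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .codes import CaseCriteria, explode_dx

logger = logging.getLogger(__name__)


class ReferentialIntegrityError(ValueError):
    """Claims reference patients absent from the person registry."""


class InsufficientPoolError(RuntimeError):
    """A case has fewer exact demographic twins available than the ratio."""


def completed_age(birth_date, ref_date) -> pd.Series:
    """Age in completed years at a reference date (calendar semantics)."""
    b = pd.to_datetime(pd.Series(np.asarray(birth_date)))
    r = pd.to_datetime(pd.Series(np.asarray(ref_date)))
    before_bday = (r.dt.month < b.dt.month) | (
        (r.dt.month == b.dt.month) & (r.dt.day < b.dt.day)
    )
    return (r.dt.year - b.dt.year - before_bday.astype(int)).to_numpy()


def _biopsy_claims(claims: pd.DataFrame, criteria: CaseCriteria) -> pd.DataFrame:
    """(patient_id, service_date) of claims carrying a biopsy procedure code."""
    proc = claims["proc"].fillna("")
    nonempty = proc != ""
    if not nonempty.any():
        return pd.DataFrame(columns=["patient_id", "service_date"])
    sub = claims.loc[nonempty, ["patient_id", "service_date"]].copy()
    hits = proc[nonempty].str.split(";").apply(
        lambda cs: any(c in criteria.biopsy_codes for c in cs)
    )
    return sub[hits.to_numpy()]


def identify_cases(claims: pd.DataFrame, persons: pd.DataFrame,
                   criteria: CaseCriteria = CaseCriteria()) -> pd.DataFrame:
    """Find qualifying patients and their index dates.

    A patient qualifies with >= `min_inpatient` inpatient qualifying claims,
    or >= `min_outpatient` outpatient qualifying claims whose first and last
    dates are >= `outpatient_gap_days` apart (equivalent to the existence of
    one qualifying pair at least that far apart). The index date is the date
    of the first claim bearing a qualifying code in any setting; patients
    without a biopsy procedure claim inside the biopsy window are dropped.
    """
    unknown = set(claims["patient_id"]) - set(persons["patient_id"])
    if unknown:
        raise ReferentialIntegrityError(
            f"{len(unknown)} claim patient ids missing from registry "
            f"(e.g. {sorted(unknown)[:3]})"
        )
    claims = claims.reset_index(drop=True)
    dx = explode_dx(claims)
    qual = dx[(dx["system"] == "icd10") & dx["code"].isin(criteria.qualifying_codes)]
    if qual.empty:
        return pd.DataFrame(columns=["patient_id", "index_date"])
    qrows = claims.loc[qual["claim_idx"].unique(),
                       ["patient_id", "service_date", "setting"]]

    grp = qrows.groupby("patient_id")
    index_date = grp["service_date"].min()
    n_inpat = grp.apply(lambda g: (g["setting"] == "inpatient").sum(),
                        include_groups=False)

    op = qrows[qrows["setting"] == "outpatient"]
    op_grp = op.groupby("patient_id")["service_date"]
    op_n = op_grp.size()
    op_span = (op_grp.max() - op_grp.min()).dt.days

    pids = index_date.index
    inpat_ok = n_inpat.reindex(pids, fill_value=0) >= criteria.min_inpatient
    op_ok = (op_n.reindex(pids, fill_value=0) >= criteria.min_outpatient) & (
        op_span.reindex(pids) >= criteria.outpatient_gap_days
    )
    qualified = pids[(inpat_ok | op_ok.fillna(False)).to_numpy()]

    cand = pd.DataFrame({
        "patient_id": qualified,
        "index_date": index_date.loc[qualified].to_numpy(),
    })

    # biopsy requirement around the index date (closed window)
    bx = _biopsy_claims(claims, criteria)
    if bx.empty:
        logger.info("identify_cases: no biopsy claims; all %d candidates dropped",
                    len(cand))
        return cand.iloc[:0].reset_index(drop=True)
    lo_off, hi_off = criteria.biopsy_window_days
    merged = cand.merge(bx, on="patient_id", how="left")
    delta = (merged["service_date"] - merged["index_date"]).dt.days
    merged["in_win"] = (delta >= lo_off) & (delta <= hi_off)
    has_bx = merged.groupby("patient_id")["in_win"].any()
    keep = cand["patient_id"].map(has_bx).fillna(False).to_numpy(dtype=bool)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("identify_cases: %d candidates dropped for missing biopsy", dropped)
    return cand[keep].sort_values("patient_id").reset_index(drop=True)


def apply_exclusions(candidates: pd.DataFrame, claims: pd.DataFrame,
                     registry_flags: pd.DataFrame | None = None,
                     criteria: CaseCriteria = CaseCriteria()):
    """Drop candidates with exclusion features; returns (kept, exclusion log).

    Rule order is fixed (first match wins): any 2015 claim with the legacy
    ICD-9 amyloidosis code -> confirmed non-AL registry record -> post-index
    switch to another amyloidosis code.
    """
    claims = claims.reset_index(drop=True)
    cand_ids = set(candidates["patient_id"])
    sub = claims[claims["patient_id"].isin(cand_ids)].reset_index(drop=True)
    dx = explode_dx(sub)

    dx_2015 = dx[(dx["system"] == "icd9")
                 & dx["code"].isin(criteria.exclusion_codes_2015)]
    prior_ids: set = set()
    if not dx_2015.empty:
        rows = sub.loc[dx_2015["claim_idx"].unique(), ["patient_id", "service_date"]]
        prior_ids = set(rows.loc[rows["service_date"].dt.year == 2015, "patient_id"])

    registry_ids: set = set()
    if registry_flags is not None and len(registry_flags):
        fl = registry_flags
        mask = [
            (s, c) in criteria.registry_nonal_codes
            for s, c in zip(fl["flag_system"], fl["flag_code"].astype(str))
        ]
        registry_ids = set(fl.loc[mask, "patient_id"]) & cand_ids

    idx_map = dict(zip(candidates["patient_id"], candidates["index_date"]))
    dx_switch = dx[(dx["system"] == "icd10") & dx["code"].isin(criteria.switch_codes)]
    switch_ids: set = set()
    if not dx_switch.empty:
        rows = sub.loc[dx_switch["claim_idx"].unique(), ["patient_id", "service_date"]]
        after = rows["service_date"] > rows["patient_id"].map(idx_map)
        switch_ids = set(rows.loc[after.to_numpy(), "patient_id"])

    log_rows = []
    for pid in sorted(cand_ids):
        if pid in prior_ids:
            log_rows.append((pid, "prior_2015"))
        elif pid in registry_ids:
            log_rows.append((pid, "registry"))
        elif pid in switch_ids:
            log_rows.append((pid, "switch"))
    log = pd.DataFrame(log_rows, columns=["patient_id", "reason"])
    kept = candidates[~candidates["patient_id"].isin(set(log["patient_id"]))]
    return kept.reset_index(drop=True), log


def _amyloidosis_claim_ids(claims: pd.DataFrame) -> set:
    """Patients with any amyloidosis-coded claim (ICD-10 E85*, ICD-9 277.3)."""
    dx = explode_dx(claims.reset_index(drop=True))
    amy = dx[((dx["system"] == "icd10") & dx["code"].str.startswith("E85"))
             | ((dx["system"] == "icd9") & (dx["code"] == "277.3"))]
    if amy.empty:
        return set()
    return set(claims.reset_index(drop=True).loc[amy["claim_idx"].unique(), "patient_id"])


def match_comparators(cases: pd.DataFrame, persons: pd.DataFrame,
                      claims: pd.DataFrame | None = None, ratio: int = 10,
                      seed: int = 0, exclude_ids: set | None = None,
                      age_fallback: bool = False) -> pd.DataFrame:
    """Exact 1:`ratio` matching on (sex, region, completed age at index).

    Comparators are drawn uniformly without replacement — each serves at
    most one case — processing cases in ascending (index_date, patient_id)
    order, deterministically for a given seed. Pool members with any
    amyloidosis-coded claim, and any id in ``exclude_ids``, are ineligible.
    Raises :class:`InsufficientPoolError` naming the first case that cannot
    be matched; ``age_fallback`` widens the age key by +/-1 year for such
    cases instead.
    """
    rng = np.random.default_rng(seed)
    excl = set(exclude_ids or ())
    excl |= set(cases["patient_id"])
    if claims is not None and len(claims):
        excl |= _amyloidosis_claim_ids(claims)
    pool = persons[~persons["patient_id"].isin(excl)].copy()
    pool = pool.sort_values("patient_id").reset_index(drop=True)

    groups: dict = {}
    for key, g in pool.groupby(["sex", "region"], sort=True):
        g = g.sort_values(["birth_date", "patient_id"], kind="mergesort")
        groups[key] = {
            "birth": g["birth_date"].to_numpy(),
            "ids": g["patient_id"].to_numpy(),
            "used": np.zeros(len(g), dtype=bool),
        }

    cases_sorted = cases.sort_values(["index_date", "patient_id"],
                                     kind="mergesort").reset_index(drop=True)
    persons_idx = persons.set_index("patient_id")
    rows = []
    for set_id, case in enumerate(cases_sorted.itertuples(index=False), start=1):
        p = persons_idx.loc[case.patient_id]
        idx = pd.Timestamp(case.index_date)
        age = int(completed_age([p["birth_date"]], [idx])[0])

        def eligible(age_lo: int, age_hi: int) -> np.ndarray:
            g = groups.get((p["sex"], p["region"]))
            if g is None:
                return np.array([], dtype=int)
            # birth in (idx - (age_hi+1) years, idx - age_lo years]
            lo = idx - pd.DateOffset(years=age_hi + 1) + pd.Timedelta(days=1)
            hi = idx - pd.DateOffset(years=age_lo)
            i0 = np.searchsorted(g["birth"], np.datetime64(lo), side="left")
            i1 = np.searchsorted(g["birth"], np.datetime64(hi), side="right")
            cand = np.arange(i0, i1)
            return cand[~g["used"][cand]]

        avail = eligible(age, age)
        if len(avail) < ratio and age_fallback:
            avail = eligible(max(age - 1, 0), age + 1)
        if len(avail) < ratio:
            raise InsufficientPoolError(
                f"case {case.patient_id}: only {len(avail)} exact twins "
                f"available for ratio {ratio}"
            )
        pick = rng.choice(avail, size=ratio, replace=False)
        g = groups[(p["sex"], p["region"])]
        g["used"][pick] = True
        rows.append((case.patient_id, "case", idx, set_id))
        for pid in sorted(g["ids"][pick]):
            rows.append((pid, "comparator", idx, set_id))

    return pd.DataFrame(rows, columns=["patient_id", "role", "index_date",
                                       "matched_set_id"])
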