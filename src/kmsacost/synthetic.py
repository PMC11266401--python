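"""Synthetic person registry and claims generator.

Emulates the statistical structure of a national claims database around a
newly diagnosed AL-amyloidosis cohort: six-region demographics, cohort-
specific comorbidity prevalence, piecewise-exponential early-excess
mortality, year-graded hurdle negative-binomial visit counts with gamma
claim costs, administrative censoring at a fixed data-end date, qualifying
diagnosis/biopsy claim patterns for cases, and configurable "trap" patterns
that the cohort-identification rule must reject.

Cases and traps are simulated on an index-anchored period grid (pre-index
year, four quarters, two half-years, one year); comparator-pool members are
simulated as a calendar-stationary process from 2015-01-01 so any reference
date yields the correct expected intensity in every window.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .calibrate import CASE_PERIODS, ProcessCalibration, covariate_scores
from .codes import DEFAULT_BIOPSY_CODES, GENERIC_DX, COMORBIDITY_CATEGORIES, DEFAULT_CODELISTS
from .config import SETTINGS, TRAP_TYPES, SyntheticConfig, derive_rng

CLAIM_COLUMNS = [
    "patient_id", "service_date", "setting", "dx", "proc",
    "medication_cost", "non_medication_cost", "inpatient_days",
]
PERSON_COLUMNS = ["patient_id", "sex", "birth_date", "region", "death_date", "enroll_end"]
TRUTH_COLUMNS = ["patient_id", "group", "latent_index_date", "progenitor_id",
                 "age_at_index"] + [f"cm_{c}" for c in COMORBIDITY_CATEGORIES]

_QUALIFYING = ("E85.4", "E85.8", "E85.9")


# ---------------------------------------------------------------------------
# persons

def generate_persons(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw cases, trap persons, and the comparator pool.

    Returns a registry frame carrying, beyond the registry columns, the
    synthetic ground truth (`group`, `latent_index_date`, `progenitor_id`,
    latent age and comorbidity indicators) used by the generator itself and
    by validation tests; `write_dataset` splits these into a separate file.
    Every case's matching key (sex, region, birth date) is cloned onto its
    pool twins, so exact 1:10 matching is feasible by construction.
    """
    if config.n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    seed = config.rng_seed if seed is None else seed
    rng = derive_rng(seed, "persons")
    n_trap = int(np.ceil(config.trap_rate * config.n_cases)) if config.trap_rate > 0 else 0
    groups = (["case"] * config.n_cases
              + [f"trap_{t}" for t in TRAP_TYPES for _ in range(n_trap)])
    n_anchor = len(groups)

    lo, hi = config.index_window_dates
    span = (hi - lo).days + 1
    idx_days = rng.integers(0, span, size=n_anchor)
    index_date = pd.to_datetime(lo) + pd.to_timedelta(idx_days, unit="D")

    band_idx = rng.choice(len(config.age_bands), size=n_anchor, p=config.age_band_probs)
    bands = np.array(config.age_bands, dtype=float)
    age = bands[band_idx, 0] + rng.random(n_anchor) * (bands[band_idx, 1] - bands[band_idx, 0])
    sex = np.where(rng.random(n_anchor) < config.p_male, "male", "female")
    region = rng.choice(config.regions, size=n_anchor, p=config.region_probs)
    birth = index_date - pd.to_timedelta(np.round(age * 365.25).astype(int), unit="D")

    anchor = pd.DataFrame({
        "patient_id": [f"{g.replace('trap_', 'trap-')}-{i:06d}" for i, g in enumerate(groups)],
        "sex": sex, "birth_date": birth, "region": region,
        "group": groups, "latent_index_date": index_date,
        "progenitor_id": [f"case-{i:06d}" if g == "case" else "" for i, g in enumerate(groups)],
        "age_at_index": age,
    })
    anchor.loc[anchor["group"] == "case", "patient_id"] = [
        f"case-{i:06d}" for i in range(config.n_cases)
    ]
    anchor.loc[anchor["group"] == "case", "progenitor_id"] = ""

    # comparator pool: clone matching keys from cases, round-robin
    prog = np.arange(config.pool_size) % config.n_cases
    cases = anchor.iloc[: config.n_cases]
    pool = pd.DataFrame({
        "patient_id": [f"pool-{i:06d}" for i in range(config.pool_size)],
        "sex": cases["sex"].to_numpy()[prog],
        "birth_date": cases["birth_date"].to_numpy()[prog],
        "region": cases["region"].to_numpy()[prog],
        "group": "pool",
        "latent_index_date": cases["latent_index_date"].to_numpy()[prog],
        "progenitor_id": cases["patient_id"].to_numpy()[prog],
        "age_at_index": cases["age_at_index"].to_numpy()[prog],
    })
    persons = pd.concat([anchor, pool], ignore_index=True)

    for cat in COMORBIDITY_CATEGORIES:
        p_case = config.comorbidity_prevalence["case"][cat]
        p_comp = config.comorbidity_prevalence["comparator"][cat]
        p = np.where(persons["group"] == "pool", p_comp, p_case)
        persons[f"cm_{cat}"] = (rng.random(len(persons)) < p).astype(int)

    persons["death_date"] = pd.NaT
    persons["enroll_end"] = pd.to_datetime(config.data_end_date)
    return persons


def generate_outcomes(persons: pd.DataFrame, config: SyntheticConfig,
                      seed: int | None = None) -> pd.DataFrame:
    """Draw death dates from cohort-specific piecewise-exponential hazards.

    Times are measured from each person's latent index/reference date; the
    death *day* is the ceiling of the continuous draw, so no death falls on
    day 0 and the product-limit weight for the first period is exactly 1.
    Death dates beyond the administrative data end are retained (follow-up
    truncates at the data end first).
    """
    seed = config.rng_seed if seed is None else seed
    rng = derive_rng(seed, "outcomes")
    out = persons.copy()
    is_case_like = (out["group"] != "pool").to_numpy()
    t = np.full(len(out), np.inf)
    for cohort, mask in (("case", is_case_like), ("comparator", ~is_case_like)):
        n = int(mask.sum())
        if n:
            t[mask] = config.mortality_model(cohort).sample(n, rng)
    death_day = np.where(np.isfinite(t), np.ceil(t), np.nan)
    death_day = np.where(death_day < 1, 1, death_day)
    # deaths many decades past the data end are equivalent to none recorded
    t = np.where(death_day > 20_000, np.inf, t)
    idx = pd.to_datetime(out["latent_index_date"])
    out["death_date"] = pd.NaT
    finite = np.isfinite(t)
    out.loc[finite, "death_date"] = idx[finite] + pd.to_timedelta(
        death_day[finite].astype(int), unit="D"
    )
    return out


# ---------------------------------------------------------------------------
# claims

def _draw_counts(rng, p_use, extra_mean, dispersion, frac, n):
    use = rng.random(n) < p_use
    k = dispersion
    nb = rng.negative_binomial(k, k / (k + extra_mean), size=n)
    base = use.astype(int) * (1 + nb)
    return rng.binomial(base, np.clip(frac, 0.0, 1.0))


def _claim_block(rng, cell, setting, who, day_lo, day_hi, los_cap, eta_c, counts, los_disp):
    """Expand per-person counts into claim rows (arrays dict).

    ``los_cap`` is each person's absolute last observable day (death/data
    end): stays may span period boundaries but not extend past it.
    """
    rep = np.repeat(np.arange(len(counts)), counts)
    if rep.size == 0:
        return None
    days = rng.integers(day_lo[rep].astype(np.int64), day_hi[rep].astype(np.int64) + 1)
    mu = cell.mu_base * np.exp(eta_c[who[rep]])
    shape = cell.cost_shape if hasattr(cell, "cost_shape") else 1.0
    total = np.round(rng.gamma(shape, mu / shape)).astype(np.int64)
    if setting == "inpatient":
        los_extra = max(cell.los_mean - 1.0, 0.01)
        los = 1 + rng.negative_binomial(los_disp, los_disp / (los_disp + los_extra), size=rep.size)
        los = np.minimum(los, los_cap[rep].astype(np.int64) - days + 1)
        los = np.maximum(los, 1)
    else:
        los = np.zeros(rep.size, dtype=np.int64)
    return {"who": who[rep], "day": days, "total": total, "los": los}


def generate_claims(outcomes: pd.DataFrame, config: SyntheticConfig,
                    seed: int | None = None) -> pd.DataFrame:
    """Simulate the claims table for the persons in ``outcomes``.

    Qualifying AL diagnosis patterns for cases are planted by relocating and
    tagging claims already drawn from the cost process, so calibrated visit
    and cost intensities are untouched; trap patterns are appended as
    dedicated claims (trap persons never enter any analysis cohort).
    """
    seed = config.rng_seed if seed is None else seed
    rng = derive_rng(seed, "claims")
    data_end = pd.to_datetime(config.data_end_date)

    eta_u, eta_c = covariate_scores(config, outcomes)
    index = pd.to_datetime(outcomes["latent_index_date"]).to_numpy()
    death = pd.to_datetime(outcomes["death_date"]).to_numpy()
    death_day = (death - index) / np.timedelta64(1, "D")
    death_day = np.where(np.isnan(death_day), np.inf, death_day)
    cens_day = (np.datetime64(data_end) - index) / np.timedelta64(1, "D")
    group = outcomes["group"].to_numpy()
    is_anchor = group != "pool"

    calib = {c: ProcessCalibration(config, c) for c in ("case", "comparator")}
    targets = {c: config.targets_for(c) for c in ("case", "comparator")}

    blocks: list[dict] = []

    def emit(rng, cohort, setting, who_idx, s_arr, last_ok, los_cap,
             period_len, year, year_len):
        n = len(who_idx)
        if n == 0:
            return
        cell = calib[cohort].cell(setting, year, period_len, year_len)
        t = targets[cohort][setting]
        frac = np.clip((last_ok - s_arr + 1) / period_len, 0.0, 1.0)
        p_use = expit(cell.alpha0 + eta_u[who_idx])
        counts = _draw_counts(rng, p_use, cell.extra_mean, t.count_dispersion, frac, n)
        live = counts > 0

        class _Cell:  # carry shape/los info alongside calibrated params
            alpha0 = cell.alpha0
            mu_base = cell.mu_base
            los_mean = cell.los_mean
            cost_shape = t.cost_shape

        blk = _claim_block(
            rng, _Cell, setting, who_idx[live],
            s_arr[live], last_ok[live], los_cap[live], eta_c, counts[live],
            t.los_dispersion,
        )
        if blk is not None:
            blk["setting"] = setting
            blk["med_frac"] = t.med_frac
            blocks.append(blk)

    # --- index-anchored persons (cases + traps): period grid around index
    anchor_idx = np.flatnonzero(is_anchor)
    if anchor_idx.size:
        dd = death_day[anchor_idx]
        cd = cens_day[anchor_idx]
        abs_cap = np.minimum(dd, cd)
        for _label, s, e, year in CASE_PERIODS:
            year_len = 365.0
            last_ok = np.minimum(abs_cap, e - 1)
            ok = last_ok >= s
            sel = anchor_idx[ok]
            if sel.size == 0:
                continue
            s_arr = np.full(sel.size, s, dtype=float)
            lo = last_ok[ok]
            for setting in SETTINGS:
                emit(rng, "case", setting, sel, s_arr, lo, abs_cap[ok],
                     float(e - s), year, year_len)

    # --- pool persons: calendar-stationary quarters from 2015-01-01
    pool_idx = np.flatnonzero(~is_anchor)
    if pool_idx.size:
        q_edges = list(pd.date_range("2015-01-01", data_end, freq="QS"))
        q_edges.append(data_end + pd.Timedelta(days=1))
        dd = death_day[pool_idx]
        cd = cens_day[pool_idx]
        idx_p = index[pool_idx]
        abs_cap = np.minimum(dd, cd)
        for qs, qe in zip(q_edges[:-1], q_edges[1:]):
            L = (qe - qs).days
            # day offsets of this quarter relative to each person's index
            s_arr = (np.datetime64(qs) - idx_p) / np.timedelta64(1, "D")
            e_arr = s_arr + L
            last_ok = np.minimum(abs_cap, e_arr - 1)
            ok = last_ok >= s_arr
            sel = pool_idx[ok]
            if sel.size == 0:
                continue
            for setting in SETTINGS:
                emit(rng, "comparator", setting, sel, s_arr[ok], last_ok[ok],
                     abs_cap[ok], float(L), 0, 365.0)

    # --- assemble raw claims
    if blocks:
        who = np.concatenate([b["who"] for b in blocks])
        day = np.concatenate([b["day"] for b in blocks]).astype(np.int64)
        total = np.concatenate([b["total"] for b in blocks])
        los = np.concatenate([b["los"] for b in blocks])
        setting = np.concatenate([np.full(len(b["who"]), b["setting"]) for b in blocks])
        med_frac = np.concatenate([np.full(len(b["who"]), b["med_frac"]) for b in blocks])
    else:
        who = np.array([], dtype=int)
        day = total = los = np.array([], dtype=np.int64)
        setting = np.array([], dtype=object)
        med_frac = np.array([], dtype=float)

    claims = pd.DataFrame({
        "who": who, "day": day, "setting": setting,
        "dx": rng.choice([f"icd10:{c}" for c in GENERIC_DX], size=len(who)) if len(who)
        else np.array([], dtype=object),
        "proc": "",
        "total": total, "med_frac": med_frac, "inpatient_days": los,
    })

    if config.plant_patterns:
        claims = _plant_patterns(claims, outcomes, config, rng, eta_c, calib,
                                 death_day, cens_day)

    med = np.round(claims["med_frac"].to_numpy() * claims["total"].to_numpy()).astype(np.int64)
    claims["medication_cost"] = med
    claims["non_medication_cost"] = claims["total"].to_numpy() - med
    claims["patient_id"] = outcomes["patient_id"].to_numpy()[claims["who"].to_numpy()]
    claims["service_date"] = pd.to_datetime(
        pd.Series(index[claims["who"].to_numpy()])
        + pd.to_timedelta(claims["day"].to_numpy(), unit="D")
    ).to_numpy()
    claims = claims.sort_values(
        ["patient_id", "service_date", "setting", "total"], kind="mergesort"
    ).reset_index(drop=True)
    return claims[CLAIM_COLUMNS].copy()


def _plant_patterns(claims, outcomes, config, rng, eta_c, calib, death_day, cens_day):
    """Tag/relocate claims to encode case criteria, traps and comorbidity.

    Operates on flat arrays and applies all edits in bulk; per-person Python
    loops are reserved for rare fallbacks (e.g. a case with no year-1
    outpatient visit to relocate).
    """
    group = outcomes["group"].to_numpy()
    n_persons = len(outcomes)
    is_case = group == "case"
    is_trap = np.char.startswith(group.astype(str), "trap_")
    last_ok_full = np.minimum(np.minimum(death_day, cens_day), 1094).astype(int)

    who_arr = claims["who"].to_numpy()
    day_arr = claims["day"].to_numpy().copy()
    dx_arr = claims["dx"].to_numpy(dtype=object).copy()
    proc_arr = np.full(len(claims), "", dtype=object)
    proc_in = claims["proc"].to_numpy(dtype=object)
    if len(claims):
        proc_arr[:] = proc_in

    extra = {k: [] for k in ("who", "day", "setting", "dx", "proc", "total",
                             "med_frac", "inpatient_days")}

    def typical_cost(setting, who):
        t = config.targets_for("case")[setting]
        cell = calib["case"].cell(setting, 1, 91.0, 365.0)
        mu = cell.mu_base * np.exp(eta_c[who])
        return int(round(rng.gamma(t.cost_shape, mu / t.cost_shape))), t.med_frac

    def append(who, day, setting, dx, proc=""):
        cost, mf = typical_cost(setting, who)
        extra["who"].append(who)
        extra["day"].append(day)
        extra["setting"].append(setting)
        extra["dx"].append(dx)
        extra["proc"].append(proc)
        extra["total"].append(cost)
        extra["med_frac"].append(mf)
        extra["inpatient_days"].append(1 if setting == "inpatient" else 0)

    def al_codes(n):
        return np.array([f"icd10:{c}" for c in _QUALIFYING])[
            rng.integers(len(_QUALIFYING), size=n)]

    def al_dx() -> str:
        return str(al_codes(1)[0])

    def tag_al(rows: np.ndarray):
        """Add an AL code to existing rows, random primary/secondary."""
        if rows.size == 0:
            return
        codes = al_codes(rows.size)
        primary = rng.random(rows.size) < 0.5
        old = dx_arr[rows]
        dx_arr[rows] = np.where(primary, codes + ";" + old, old + ";" + codes)

    set_arr = claims["setting"].to_numpy()
    op_mask = set_arr == "outpatient"
    ip_mask = set_arr == "inpatient"
    case_ids = np.flatnonzero(is_case)

    def first_claim_row(person_sel, claim_mask) -> dict:
        """Row index of each selected person's earliest claim in the mask."""
        sub = pd.DataFrame({
            "who": who_arr[claim_mask], "day": day_arr[claim_mask],
            "row": np.flatnonzero(claim_mask),
        })
        sub = sub[np.isin(sub["who"], person_sel)]
        if sub.empty:
            return {}
        sub = sub.sort_values(["who", "day", "row"], kind="mergesort")
        first = sub.groupby("who", sort=False).first()
        return dict(zip(first.index, first["row"]))

    # (a) relocate each case's earliest year-1 outpatient visit to day 0, tag AL
    y1_op = op_mask & (day_arr >= 0) & (day_arr < 365)
    first_map = first_claim_row(case_ids, y1_op)
    rows = np.array([first_map[w] for w in case_ids if w in first_map], dtype=int)
    day_arr[rows] = 0
    tag_al(rows)
    for w in case_ids:
        if w not in first_map:
            append(w, 0, "outpatient", al_dx())

    # (b) complete the rule: inpatient AL claim if one exists, else a second
    # outpatient AL claim >= 30 days after index
    ip_win = ip_mask & (day_arr >= 0) & (day_arr <= 1094)
    ip_map = first_claim_row(case_ids, ip_win)
    tag_al(np.array(sorted(ip_map.values()), dtype=int))
    need_op2 = np.array([w for w in case_ids if w not in ip_map], dtype=int)
    op2 = op_mask & (day_arr >= 30) & (day_arr <= 1094)
    op2_map = first_claim_row(need_op2, op2)
    ok_rows = []
    for w in need_op2:
        row = op2_map.get(w)
        if row is not None and day_arr[row] <= last_ok_full[w]:
            ok_rows.append(row)
        elif last_ok_full[w] >= 30:
            append(w, int(rng.integers(30, min(91, last_ok_full[w] + 1))),
                   "outpatient", al_dx())
        else:  # died within 30 days with no later visit: inpatient route
            append(w, max(0, last_ok_full[w]), "inpatient", al_dx())
    tag_al(np.array(ok_rows, dtype=int))

    # ---- trap patterns ----------------------------------------------------
    for ttype in ("single_outpatient", "short_gap", "no_biopsy", "prior_2015",
                  "code_switch", "registry_nonal"):
        for w in np.flatnonzero(group == f"trap_{ttype}"):
            if ttype == "single_outpatient":
                append(w, 0, "outpatient", al_dx())
            elif ttype == "short_gap":
                append(w, 0, "outpatient", al_dx())
                append(w, min(15, max(1, last_ok_full[w])), "outpatient", al_dx())
            else:  # inpatient-qualifying core, then the excluding feature
                append(w, 0, "inpatient", al_dx())
                if ttype == "prior_2015":
                    idx_date = pd.Timestamp(outcomes["latent_index_date"].iloc[w])
                    append(w, (pd.Timestamp("2015-06-15") - idx_date).days,
                           "outpatient", "icd9:277.3")
                elif ttype == "code_switch":
                    append(w, min(120, max(1, last_ok_full[w])), "outpatient",
                           "icd10:E85.1")

    # ---- biopsy procedure claims ------------------------------------------
    needs_biopsy = np.flatnonzero(is_case | (is_trap & (group != "trap_no_biopsy")))
    bx_win = op_mask & (day_arr >= -300) & (day_arr <= -10)
    bx_map = first_claim_row(needs_biopsy, bx_win)
    tagged = np.array([bx_map[w] for w in needs_biopsy if w in bx_map], dtype=int)
    bx_codes = np.array(DEFAULT_BIOPSY_CODES, dtype=object)
    proc_arr[tagged] = bx_codes[rng.integers(len(bx_codes), size=tagged.size)]
    for w in needs_biopsy:
        if w not in bx_map:
            append(w, -60, "outpatient", f"icd10:{GENERIC_DX[0]}",
                   proc=str(bx_codes[rng.integers(len(bx_codes))]))

    # ---- comorbidity claim planting (all groups) --------------------------
    suffix = np.full(n_persons, "", dtype=object)
    for cat in COMORBIDITY_CATEGORIES:
        code = DEFAULT_CODELISTS[cat]["icd10"][0]
        pos = outcomes[f"cm_{cat}"].to_numpy() == 1
        suffix[pos] = suffix[pos] + f";icd10:{code}"
    has_cm = suffix != ""

    base_op = op_mask & (day_arr >= -365) & (day_arr <= -1)
    sub = pd.DataFrame({
        "who": who_arr[base_op], "day": day_arr[base_op],
        "row": np.flatnonzero(base_op),
    })
    sub = sub[has_cm[sub["who"].to_numpy()]]
    sub = sub.sort_values(["who", "day", "row"], kind="mergesort")
    sub["rank"] = sub.groupby("who", sort=False).cumcount()
    tag = sub[sub["rank"] < 2]
    rows = tag["row"].to_numpy()
    dx_arr[rows] = dx_arr[rows] + suffix[tag["who"].to_numpy()]
    n_tagged = tag.groupby("who").size()
    for w in np.flatnonzero(has_cm):
        for j in range(2 - int(n_tagged.get(w, 0))):
            append(w, int(-200 + 100 * j), "outpatient",
                   f"icd10:{GENERIC_DX[1]}" + suffix[w])

    claims = claims.assign(day=day_arr, dx=dx_arr, proc=proc_arr)
    if extra["who"]:
        add = pd.DataFrame({
            "who": np.array(extra["who"], dtype=int),
            "day": np.array(extra["day"], dtype=np.int64),
            "setting": extra["setting"], "dx": extra["dx"], "proc": extra["proc"],
            "total": np.array(extra["total"], dtype=np.int64),
            "med_frac": np.array(extra["med_frac"], dtype=float),
            "inpatient_days": np.array(extra["inpatient_days"], dtype=np.int64),
        })
        claims = pd.concat([claims, add], ignore_index=True)
    return claims


def generate_registry_flags(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Catastrophic-illness-style non-AL registry flags for planted traps."""
    sel = outcomes.loc[outcomes["group"] == "trap_registry_nonal", "patient_id"]
    return pd.DataFrame({
        "patient_id": sel.to_numpy(),
        "flag_system": "icd10",
        "flag_code": "E85.1",
    })


def planted_case_ids(outcomes: pd.DataFrame) -> set[str]:
    """Ground-truth identifiers of non-trap cases."""
    return set(outcomes.loc[outcomes["group"] == "case", "patient_id"])


# ---------------------------------------------------------------------------
# claim-free fast path

def simulate_period_totals(outcomes: pd.DataFrame, config: SyntheticConfig,
                           seed: int | None = None) -> pd.DataFrame:
    """Draw patient x period panel cells directly, without claim rows.

    Distributionally identical to aggregating `generate_claims` over the
    follow-up periods (a sum of iid gamma claim costs is drawn as a single
    gamma with summed shape), up to per-claim integer rounding and the
    truncation of inpatient stays at death, which the fast path omits. Used
    where many replicate datasets are needed (bootstrap calibration
    experiments); the claim-level path remains the reference.
    """
    from .panel import COMPONENTS, PERIOD_SCHEME  # local import to avoid cycle

    seed = config.rng_seed if seed is None else seed
    rng = derive_rng(seed, "fastpanel")
    eta_u, eta_c = covariate_scores(config, outcomes)
    index = pd.to_datetime(outcomes["latent_index_date"]).to_numpy()
    death = pd.to_datetime(outcomes["death_date"]).to_numpy()
    death_day = (death - index) / np.timedelta64(1, "D")
    death_day = np.where(np.isnan(death_day), np.inf, death_day)
    cens_day = (np.datetime64(pd.to_datetime(config.data_end_date)) - index) \
        / np.timedelta64(1, "D")
    cohorts = np.where(outcomes["group"].to_numpy() == "pool", "comparator", "case")
    calib = {c: ProcessCalibration(config, c) for c in np.unique(cohorts)}

    frames = []
    n = len(outcomes)
    for p, (s, e) in enumerate(PERIOD_SCHEME.bounds, start=1):
        L = float(e - s)
        last_ok = np.minimum(np.minimum(death_day, cens_day), e - 1)
        frac = np.clip((last_ok - s + 1) / L, 0.0, 1.0)
        entered = np.minimum(death_day, cens_day + 1) > s
        died_within = entered & (death_day < e) & (death_day <= cens_day)
        complete = entered & ~died_within & (cens_day + 1 >= e)
        status = np.where(~entered, "not_entered",
                          np.where(died_within, "died_within",
                                   np.where(complete, "complete", "censored_within")))
        cols = {c: np.zeros(n) for c in COMPONENTS}
        year = 1 if e <= 365 else (2 if e <= 730 else 3)
        for cohort in calib:
            m = (cohorts == cohort) & entered
            if not m.any():
                continue
            for setting in SETTINGS:
                t = config.targets_for(cohort)[setting]
                cell = calib[cohort].cell(setting, year, L, 365.0)
                p_use = expit(cell.alpha0 + eta_u[m])
                counts = _draw_counts(rng, p_use, cell.extra_mean,
                                      t.count_dispersion, frac[m], int(m.sum()))
                mu = cell.mu_base * np.exp(eta_c[m])
                cost = np.zeros(len(counts))
                pos = counts > 0
                cost[pos] = rng.gamma(t.cost_shape * counts[pos],
                                      mu[pos] / t.cost_shape)
                cost = np.round(cost)
                key = {"outpatient": ("visits_outpatient", "cost_outpatient"),
                       "emergency": ("visits_emergency", "cost_emergency"),
                       "inpatient": ("admissions", "cost_inpatient")}[setting]
                cols[key[0]][m] += counts
                cols[key[1]][m] += cost
                cols["cost_total"][m] += cost
                med = np.round(t.med_frac * cost)
                cols["cost_medication"][m] += med
                cols["cost_nonmedication"][m] += cost - med
                if setting == "inpatient":
                    ld = t.los_dispersion
                    extra_mean = max((cell.los_mean or 1.0) - 1.0, 0.01)
                    days = np.zeros(len(counts))
                    days[pos] = counts[pos] + rng.negative_binomial(
                        ld * counts[pos], ld / (ld + extra_mean), size=int(pos.sum())
                    )
                    cols["hospital_days"][m] += days
        frame = pd.DataFrame({
            "patient_id": outcomes["patient_id"].to_numpy(),
            "role": np.where(cohorts == "case", "case", "comparator"),
            "period": p, "status": status,
        })
        for c in COMPONENTS:
            frame[c] = cols[c]
            frame[f"any_{c}"] = (cols[c] > 0).astype(int)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out.loc[out["status"] == "not_entered", list(COMPONENTS)] = 0.0
    return out.sort_values(["patient_id", "period"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# dataset I/O

def write_dataset(outcomes: pd.DataFrame, claims: pd.DataFrame, path,
                  registry_flags: pd.DataFrame | None = None,
                  config: SyntheticConfig | None = None,
                  seed: int | None = None) -> dict:
    """Write persons/claims/truth CSVs plus a manifest; returns the manifest.

    The registry file carries only the administrative columns; generator
    ground truth (cohort labels, latent dates, planted comorbidity) goes to
    ``truth.csv`` — synthetic provenance, never read by the pipeline.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    persons_out = outcomes[PERSON_COLUMNS].copy()
    for col in ("birth_date", "death_date", "enroll_end"):
        persons_out[col] = pd.to_datetime(persons_out[col]).dt.strftime("%Y-%m-%d")
    persons_out.to_csv(path / "persons.csv", index=False)

    truth_cols = [c for c in TRUTH_COLUMNS if c in outcomes.columns]
    truth = outcomes[truth_cols].copy()
    if "latent_index_date" in truth:
        truth["latent_index_date"] = pd.to_datetime(
            truth["latent_index_date"]).dt.strftime("%Y-%m-%d")
    truth.to_csv(path / "truth.csv", index=False)

    claims_out = claims[CLAIM_COLUMNS].copy()
    claims_out["service_date"] = pd.to_datetime(
        claims_out["service_date"]).dt.strftime("%Y-%m-%d")
    claims_out.to_csv(path / "claims.csv", index=False)

    if registry_flags is not None:
        registry_flags.to_csv(path / "registry_flags.csv", index=False)

    manifest = {
        "schema_version": 1,
        "seed": seed if seed is not None else (config.rng_seed if config else None),
        "config_hash": config.config_hash() if config else None,
        "n_persons": int(len(persons_out)),
        "n_claims": int(len(claims_out)),
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_dataset(path) -> dict[str, pd.DataFrame]:
    """Read back a written dataset; inverse of `write_dataset`."""
    path = Path(path)
    persons = pd.read_csv(path / "persons.csv",
                          parse_dates=["birth_date", "death_date", "enroll_end"])
    claims = pd.read_csv(path / "claims.csv", parse_dates=["service_date"],
                         keep_default_na=False,
                         dtype={"dx": str, "proc": str})
    out = {"persons": persons, "claims": claims}
    truth_path = path / "truth.csv"
    if truth_path.exists():
        out["truth"] = pd.read_csv(truth_path, parse_dates=["latent_index_date"])
    flags_path = path / "registry_flags.csv"
    if flags_path.exists():
        out["registry_flags"] = pd.read_csv(flags_path)
    with open(path / "manifest.json") as fh:
        out["manifest"] = json.load(fh)
    return out
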