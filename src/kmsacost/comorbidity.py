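"""Baseline comorbidity flagging and the cohort-comparison table.

Comorbidities in six categories (cardiac, liver, renal, pulmonary,
neuropathy, malignancy) are ascertained from claims in the 365 days before
the index/reference date: a category is present with at least one inpatient
claim or at least two outpatient claims bearing a category code (prefix
match, any diagnosis position, no date-gap requirement — two same-day
outpatient claims count as two). The baseline table reports the usual
descriptives with pooled-variance t-tests for continuous variables and
Pearson chi-square tests without continuity correction for categorical
ones, mirroring claims-study convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .codes import COMORBIDITY_CATEGORIES, CodeList, explode_dx, match_prefix
from .cohort import completed_age

BASELINE_WINDOW_DAYS = (-365, -1)  # closed, relative to index


def flag_comorbidities(cohort: pd.DataFrame, claims: pd.DataFrame,
                       codelists: tuple[CodeList, ...]) -> pd.DataFrame:
    """One row per cohort member with six 0/1 indicators."""
    cats = [c.category for c in codelists]
    if set(cats) - set(COMORBIDITY_CATEGORIES):
        raise ValueError(f"unknown categories: {set(cats) - set(COMORBIDITY_CATEGORIES)}")

    claims = claims.reset_index(drop=True)
    sub = claims[claims["patient_id"].isin(set(cohort["patient_id"]))]
    idx_map = dict(zip(cohort["patient_id"], pd.to_datetime(cohort["index_date"])))
    delta = (sub["service_date"] - sub["patient_id"].map(idx_map)).dt.days
    lo, hi = BASELINE_WINDOW_DAYS
    sub = sub[(delta >= lo) & (delta <= hi)]
    dx = explode_dx(sub.reset_index(drop=True))
    sub = sub.reset_index(drop=True)

    out = pd.DataFrame({"patient_id": cohort["patient_id"].to_numpy()})
    for cl in codelists:
        hit = pd.Series(False, index=dx.index)
        for system, prefixes in (("icd9", cl.icd9_codes), ("icd10", cl.icd10_codes)):
            if prefixes:
                m = (dx["system"] == system) & match_prefix(dx["code"], tuple(prefixes))
                hit |= m
        rows = dx.loc[hit, "claim_idx"].unique()
        hits = sub.loc[rows, ["patient_id", "setting"]]
        n_ip = hits[hits["setting"] == "inpatient"].groupby("patient_id").size()
        n_op = hits[hits["setting"] == "outpatient"].groupby("patient_id").size()
        flag = (
            out["patient_id"].map(n_ip).fillna(0).ge(1)
            | out["patient_id"].map(n_op).fillna(0).ge(2)
        )
        out[cl.category] = flag.astype(int)
    for cat in COMORBIDITY_CATEGORIES:
        if cat not in out.columns:
            out[cat] = 0
    return out[["patient_id", *COMORBIDITY_CATEGORIES]]


def _chi2_p(case_counts: np.ndarray, comp_counts: np.ndarray) -> float:
    """Pearson chi-square without continuity correction; p=1 on zero statistic."""
    table = np.array([case_counts, comp_counts], dtype=float)
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2 or table.sum(axis=1).min() == 0:
        return float("nan")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def _ttest_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided pooled-variance t-test; NaN when degenerate."""
    if len(x) < 2 or len(y) < 2 or (np.var(x) == 0 and np.var(y) == 0):
        return float("nan")
    return float(stats.ttest_ind(x, y, equal_var=True).pvalue)


def baseline_table(cohort: pd.DataFrame, persons: pd.DataFrame,
                   profiles: pd.DataFrame, welch: bool = False) -> pd.DataFrame:
    """Demographic/clinical comparison of matched cohorts with tests.

    Long format: one row per variable level with n/% (or mean/SD and
    median/IQR for age) per cohort and a single p-value per variable.
    """
    p = persons.set_index("patient_id")
    df = cohort.merge(profiles, on="patient_id", how="left")
    df["sex"] = df["patient_id"].map(p["sex"])
    df["region"] = df["patient_id"].map(p["region"])
    birth = df["patient_id"].map(p["birth_date"])
    df["age"] = (pd.to_datetime(df["index_date"]) - pd.to_datetime(birth)).dt.days / 365.25
    df["age_years"] = completed_age(birth.to_numpy(), df["index_date"].to_numpy())

    is_case = df["role"] == "case"
    ca, co = df[is_case], df[~is_case]
    n_ca, n_co = len(ca), len(co)
    rows = []

    def add(variable, level, case_n=None, comp_n=None, case_stat=None,
            comp_stat=None, pval=None, test=None):
        rows.append({
            "variable": variable, "level": level,
            "case_n": case_n, "case_pct_or_mean": case_stat,
            "comp_n": comp_n, "comp_pct_or_mean": comp_stat,
            "p_value": pval, "test": test,
        })

    # gender
    counts = [( (ca["sex"] == s).sum(), (co["sex"] == s).sum() ) for s in ("male", "female")]
    pv = _chi2_p([c[0] for c in counts], [c[1] for c in counts])
    for (s, (a, b)) in zip(("male", "female"), counts):
        add("gender", s, a, b, 100 * a / n_ca, 100 * b / n_co,
            pv if s == "male" else None, "chi2" if s == "male" else None)

    # age: mean/SD, median/IQR, bands
    if welch:
        pv = float(stats.ttest_ind(ca["age"], co["age"], equal_var=False).pvalue)
        tname = "welch_t"
    else:
        pv = _ttest_p(ca["age"].to_numpy(), co["age"].to_numpy())
        tname = "t"
    add("age", "mean_sd", n_ca, n_co,
        f"{ca['age'].mean():.2f} ± {ca['age'].std():.2f}",
        f"{co['age'].mean():.2f} ± {co['age'].std():.2f}", pv, tname)
    add("age", "median_iqr", n_ca, n_co,
        f"{ca['age'].median():.2f} ({ca['age'].quantile(.25):.2f}, {ca['age'].quantile(.75):.2f})",
        f"{co['age'].median():.2f} ({co['age'].quantile(.25):.2f}, {co['age'].quantile(.75):.2f})",
        None, None)
    bands = [(0, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 79), (80, 200)]
    band_counts = []
    for lo, hi in bands:
        a = ((ca["age_years"] >= lo) & (ca["age_years"] <= hi)).sum()
        b = ((co["age_years"] >= lo) & (co["age_years"] <= hi)).sum()
        band_counts.append((a, b))
    pv_band = _chi2_p([c[0] for c in band_counts], [c[1] for c in band_counts])
    for (lo, hi), (a, b) in zip(bands, band_counts):
        label = f"<={hi}" if lo == 0 else (f">={lo}" if hi == 200 else f"{lo}-{hi}")
        add("age_band", label, a, b, 100 * a / n_ca, 100 * b / n_co,
            pv_band if lo == 0 else None, "chi2" if lo == 0 else None)

    # region
    regions = sorted(df["region"].dropna().unique())
    counts = [((ca["region"] == r).sum(), (co["region"] == r).sum()) for r in regions]
    pv = _chi2_p([c[0] for c in counts], [c[1] for c in counts])
    for r, (a, b) in zip(regions, counts):
        add("region", r, a, b, 100 * a / n_ca, 100 * b / n_co,
            pv if r == regions[0] else None, "chi2" if r == regions[0] else None)

    # comorbidities: one 2x2 test per category
    for cat in COMORBIDITY_CATEGORIES:
        a, b = int(ca[cat].sum()), int(co[cat].sum())
        pv = _chi2_p([a, n_ca - a], [b, n_co - b])
        add("comorbidity", cat, a, b, 100 * a / n_ca, 100 * b / n_co, pv, "chi2")

    out = pd.DataFrame(rows)
    out.attrs["n_case"] = n_ca
    out.attrs["n_comparator"] = n_co
    return out
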