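"""Study orchestration, significance tests, and report assembly.

`run_study` wires the whole pipeline: simulate a registry and claims,
identify and match the cohorts, flag comorbidities, build the cost panel,
fit Kaplan-Meier curves and per-period two-part models, weight and sum to
KMSA cumulative estimates, bootstrap the estimation, and write table- and
figure-shaped CSV artifacts plus a manifest. All randomness flows from a
single top-level seed through documented per-stage derived seeds.
"""

from __future__ import annotations

import json
import logging
import math
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import synthetic
from .codes import CaseCriteria, default_codelists
from .cohort import apply_exclusions, identify_cases, match_comparators
from .comorbidity import baseline_table, flag_comorbidities
from .config import SyntheticConfig
from .bootstrap import bootstrap_kmsa
from .panel import (COMPONENTS, COST_COMPONENTS, PERIOD_SCHEME, build_panel,
                    crude_annual_summary, pre_index_summary)
from .survival import km_fit, survival_inputs
from .twopart import (HORIZONS, design_matrix, fit_two_part, incremental_cost,
                      kmsa_cumulative)

logger = logging.getLogger(__name__)

DEFAULT_BOOTSTRAP_COMPONENTS = ("cost_total", "cost_medication", "cost_nonmedication")


def share_of_first_year(incremental: dict[int, float]) -> int | None:
    """Percent of the 3-year attributable quantity incurred in year 1.

    Rounded to a whole percent, half away from zero; undefined (None) when
    the 3-year denominator is zero.
    """
    three = incremental.get(1095)
    one = incremental.get(365)
    if three in (None, 0) or one is None:
        return None
    x = 100.0 * one / three
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def observed_totals_test(panel: pd.DataFrame, component: str) -> float:
    """Two-sample t-test p-value on per-patient observed 3-year totals."""
    totals = panel.groupby(["role", "patient_id"])[component].sum()
    a = totals.loc["case"].to_numpy()
    b = totals.loc["comparator"].to_numpy()
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_study(config: SyntheticConfig, seed: int, outdir=None, B: int = 1000,
              ratio: int = 10, criteria: CaseCriteria = CaseCriteria(),
              codelists=None, scheme=PERIOD_SCHEME,
              components: tuple[str, ...] = COMPONENTS,
              bootstrap_components: tuple[str, ...] = DEFAULT_BOOTSTRAP_COMPONENTS,
              write_claims: bool = True) -> dict:
    """Execute the full synthetic study end-to-end; returns the report bundle."""
    t0 = time.time()
    codelists = codelists or default_codelists()
    seeds = _stage_seeds(seed)
    bundle: dict = {"seed": seed, "config_hash": config.config_hash()}

    def stage(name):
        logger.info("[%7.1fs] stage: %s", time.time() - t0, name)

    # 1. simulate index-anchored persons (cases + traps) and their claims
    stage("simulate")
    persons = synthetic.generate_persons(config, seeds[0])
    anchor = persons[persons["group"] != "pool"].reset_index(drop=True)
    anchor = synthetic.generate_outcomes(anchor, config, seeds[1])
    claims_anchor = synthetic.generate_claims(anchor, config, seeds[2])
    registry_flags = synthetic.generate_registry_flags(anchor)

    # 2. cohort identification, exclusions, matching
    stage("build-cohort")
    candidates = identify_cases(claims_anchor, persons, criteria)
    kept, exclusions = apply_exclusions(candidates, claims_anchor,
                                        registry_flags, criteria)
    cohort = match_comparators(
        kept, persons, claims=claims_anchor, ratio=ratio, seed=seeds[3],
        exclude_ids=set(anchor["patient_id"]),
    )

    # 3. comparator outcomes/claims relative to their assigned reference date
    stage("comparator-claims")
    comp_ids = cohort.loc[cohort["role"] == "comparator", "patient_id"]
    ref_map = dict(zip(cohort["patient_id"], cohort["index_date"]))
    comp = persons[persons["patient_id"].isin(set(comp_ids))].copy()
    comp["latent_index_date"] = comp["patient_id"].map(ref_map)
    comp = synthetic.generate_outcomes(comp, config, seeds[4])
    claims_comp = synthetic.generate_claims(comp, config, seeds[5])

    outcomes = pd.concat([anchor, comp], ignore_index=True)
    claims = pd.concat([claims_anchor, claims_comp], ignore_index=True)

    # 4. comorbidity, panel, survival
    stage("panel")
    profiles = flag_comorbidities(cohort, claims, codelists)
    table1 = baseline_table(cohort, outcomes, profiles)
    panel = build_panel(cohort, claims, outcomes, scheme)
    crude = crude_annual_summary(panel, scheme)
    pre_index = pre_index_summary(cohort, claims)
    surv = survival_inputs(cohort, outcomes)
    curves = {r: km_fit(surv[surv["patient_id"].isin(
        set(cohort.loc[cohort["role"] == r, "patient_id"]))])
        for r in ("case", "comparator")}

    # 5. two-part fits, recycled predictions, KMSA cumulatives
    stage("kmsa")
    X_by_role = {}
    fits_json = {}
    estimates = []
    incrementals = {}
    for role in ("case", "comparator"):
        sub = cohort[cohort["role"] == role]
        X_by_role[role] = design_matrix(sub, outcomes, profiles)
    for comp_name in components:
        ests = {}
        for role in ("case", "comparator"):
            fits = {
                p: fit_two_part(panel, X_by_role[role], role, comp_name, p)
                for p in range(1, scheme.n_periods + 1)
            }
            est = kmsa_cumulative(fits, curves[role], X_by_role[role], scheme)
            ests[role] = est
            for p, f in fits.items():
                fits_json[f"{role}/{comp_name}/{p}"] = {
                    "part1_params": None if f.part1_params is None
                    else list(map(float, f.part1_params)),
                    "part1_prob": f.part1_prob,
                    "part2_params": None if f.part2_params is None
                    else list(map(float, f.part2_params)),
                    "part2_mean": f.part2_mean,
                    "family": f.family, "n_fit": f.n_fit, "n_pos": f.n_pos,
                    "notes": f.notes,
                }
            for h, v in est.cumulative.items():
                estimates.append((role, comp_name, h, v))
        inc = incremental_cost(ests["case"], ests["comparator"])
        incrementals[comp_name] = inc
        for h, v in inc.items():
            estimates.append(("incremental", comp_name, h, v))
    kmsa_df = pd.DataFrame(estimates,
                           columns=["cohort", "component", "horizon", "estimate"])

    # 6. bootstrap + tests
    stage("bootstrap")
    summaries, _reps = bootstrap_kmsa(
        panel, X_by_role, surv, bootstrap_components, B=B, seed=seeds[6],
        scheme=scheme,
    )
    boot_df = pd.DataFrame([{
        "estimand": s.estimand, "B": s.B, "mean": s.mean, "sd": s.sd,
        "ci_low": s.ci_low, "ci_high": s.ci_high,
    } for s in summaries])
    pvals = {c: observed_totals_test(panel, c) for c in bootstrap_components}

    shares = {c: share_of_first_year(incrementals[c])
              for c in ("cost_total", "cost_medication", "cost_nonmedication")
              if c in incrementals}

    bundle.update({
        "n_cases": int((cohort["role"] == "case").sum()),
        "n_comparators": int((cohort["role"] == "comparator").sum()),
        "table1": table1, "kmsa_estimates": kmsa_df, "bootstrap": boot_df,
        "crude_summary": crude, "pre_index_summary": pre_index,
        "incrementals": incrementals, "share_of_first_year": shares,
        "p_values_observed_totals": pvals,
        "exclusions": exclusions, "cohort": cohort, "panel": panel,
        "curves": curves, "profiles": profiles,
        "outcomes": outcomes, "claims": claims,
        "registry_flags": registry_flags,
    })

    if outdir is not None:
        stage("write")
        _write_bundle(bundle, outdir, config, seed, fits_json,
                      write_claims=write_claims)
    stage("done")
    return bundle


def _write_bundle(bundle, outdir, config, seed, fits_json, write_claims=True):
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "figures").mkdir(exist_ok=True)

    if write_claims:
        synthetic.write_dataset(bundle["outcomes"], bundle["claims"], out,
                                bundle["registry_flags"], config, seed)
    bundle["cohort"].to_csv(out / "cohort.csv", index=False)
    bundle["exclusions"].to_csv(out / "exclusions.csv", index=False)
    bundle["profiles"].to_csv(out / "comorbidity.csv", index=False)
    bundle["table1"].to_csv(out / "table1.csv", index=False)
    bundle["panel"].to_csv(out / "panel.csv", index=False)
    bundle["crude_summary"].to_csv(out / "crude_summary.csv", index=False)
    bundle["crude_summary"].to_csv(out / "figures" / "crude_annual.csv", index=False)
    bundle["pre_index_summary"].to_csv(out / "pre_index_summary.csv", index=False)
    for role, curve in bundle["curves"].items():
        curve.to_frame().to_csv(out / f"km_curve_{role}.csv", index=False)
        curve.to_frame().to_csv(out / "figures" / f"km_{role}.csv", index=False)
    bundle["kmsa_estimates"].to_csv(out / "kmsa_estimates.csv", index=False)
    kd = bundle["kmsa_estimates"]
    kd[kd["component"].isin(COST_COMPONENTS)].to_csv(
        out / "cumulative_costs_by_setting.csv", index=False)
    kd[kd["component"].isin(("cost_medication", "cost_nonmedication",
                             "cost_total"))].to_csv(
        out / "cumulative_costs_by_medication.csv", index=False)
    bundle["bootstrap"].to_csv(out / "bootstrap_summaries.csv", index=False)
    with open(out / "two_part_fits.json", "w") as fh:
        json.dump(fits_json, fh, indent=1, sort_keys=True)
    manifest = {
        "seed": seed,
        "config_hash": bundle["config_hash"],
        "n_cases": bundle["n_cases"],
        "n_comparators": bundle["n_comparators"],
        "share_of_first_year": bundle["share_of_first_year"],
        "p_values_observed_totals": bundle["p_values_observed_totals"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
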