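import numpy as np
import pandas as pd
import pytest

import kmsacost as k
from kmsacost.calibrate import covariate_scores
from kmsacost.config import analytic_mean_age


@pytest.fixture(scope="module")
def gen(small_cfg):
    persons = k.generate_persons(small_cfg, 7)
    anchor = persons[persons["group"] != "pool"].reset_index(drop=True)
    anchor = k.generate_outcomes(anchor, small_cfg, 7)
    claims = k.generate_claims(anchor, small_cfg, 7)
    return small_cfg, persons, anchor, claims


def test_generation_is_deterministic(small_cfg):
    a = k.generate_persons(small_cfg, 3)
    b = k.generate_persons(small_cfg, 3)
    pd.testing.assert_frame_equal(a, b)
    oa = k.generate_outcomes(a, small_cfg, 3)
    ob = k.generate_outcomes(b, small_cfg, 3)
    pd.testing.assert_frame_equal(oa, ob)
    ca = k.generate_claims(oa.head(300), small_cfg, 3)
    cb = k.generate_claims(ob.head(300), small_cfg, 3)
    pd.testing.assert_frame_equal(ca, cb)


def test_sex_draws_follow_binomial_sampling(small_cfg):
    n = 100_000
    cfg = small_cfg.with_(n_cases=n, comparator_pool_size=0, trap_rate=0.0)
    persons = k.generate_persons(cfg, 21)
    p = 0.5907
    frac = (persons["sex"] == "male").mean()
    se = np.sqrt(p * (1 - p) / n)
    assert abs(frac - p) < 3 * se


def test_mean_age_matches_cohort_calibration(small_cfg):
    cfg = small_cfg.with_(n_cases=10_000, comparator_pool_size=0, trap_rate=0.0)
    persons = k.generate_persons(cfg, 8)
    mu = analytic_mean_age(cfg)
    assert abs(mu - 60.78) < 0.1  # band mixture mean matches the cohort mean
    assert abs(persons["age_at_index"].mean() - mu) < 3 * 14.2 / np.sqrt(10_000)


def test_every_case_has_ten_exact_twins(gen):
    _cfg, persons, _anchor, _claims = gen
    cases = persons[persons["group"] == "case"]
    pool = persons[persons["group"] == "pool"]
    key = ["sex", "region", "birth_date"]
    pool_counts = pool.groupby(key).size()
    case_keys = pd.MultiIndex.from_frame(cases[key])
    assert (pool_counts.reindex(case_keys).fillna(0) >= 10).all()


def test_degenerate_demographics_are_identical_on_match_keys():
    cfg = k.default_config(
        n_cases=20, comparator_pool_size=0, trap_rate=0.0,
        p_male=1.0, region_probs=(1.0, 0, 0, 0, 0, 0),
        age_bands=((50, 50.0001),), age_band_probs=(1.0,),
        index_window=("2016-06-01", "2016-06-01"),
    )
    persons = k.generate_persons(cfg, 5)
    assert persons["sex"].nunique() == 1
    assert persons["region"].nunique() == 1
    assert persons["birth_date"].nunique() == 1


def test_invalid_probability_vector_rejected():
    with pytest.raises(ValueError):
        k.default_config(region_probs=(0.5, 0.1, 0.1, 0.1, 0.1, 0.2))


def test_six_month_mortality_is_analytic(small_cfg):
    m = small_cfg.mortality_model("case")
    np.testing.assert_allclose(m.cdf(182.0), 0.121, rtol=1e-12)
    np.testing.assert_allclose(m.cdf(1095.0), 0.188, rtol=1e-12)
    mc = small_cfg.mortality_model("comparator")
    np.testing.assert_allclose(mc.cdf([182.0, 1095.0]), [0.009, 0.037], rtol=1e-12)


def test_no_claim_after_death_or_data_end(gen):
    cfg, _persons, anchor, claims = gen
    p = anchor.set_index("patient_id")
    death = claims["patient_id"].map(p["death_date"])
    end = pd.Timestamp(cfg.data_end)
    limit = death.fillna(end).clip(upper=end)
    assert (claims["service_date"] <= limit).all()


def test_claim_cost_components_are_consistent(gen):
    _cfg, _persons, _anchor, claims = gen
    assert (claims["medication_cost"] >= 0).all()
    assert (claims["non_medication_cost"] >= 0).all()
    ip = claims["setting"] == "inpatient"
    assert (claims.loc[ip, "inpatient_days"] >= 1).all()
    assert (claims.loc[~ip, "inpatient_days"] == 0).all()


def test_generated_cases_satisfy_identification_rule(gen):
    """Cross-module contract: planted non-trap cases are exactly recovered."""
    _cfg, persons, anchor, claims = gen
    cand = k.identify_cases(claims, persons)
    kept, _log = k.apply_exclusions(cand, claims, k.generate_registry_flags(anchor))
    assert set(kept["patient_id"]) == k.planted_case_ids(anchor)


def test_zero_rate_process_yields_empty_claims():
    zero = {s: t.__class__(**{**t.__dict__, "visits": (0.0,), "cost": (0.0,),
                              "p_use": (0.5,),
                              "hospital_days": (0.0,) if t.hospital_days else None})
            for s, t in k.default_config().comparator_targets.items()}
    cfg = k.default_config(
        n_cases=10, comparator_pool_size=0, trap_rate=0.0, plant_patterns=False,
        case_targets=zero, comparator_targets=zero,
        comorbidity_prevalence={"case": dict.fromkeys(
            ("cardiac", "liver", "renal", "pulmonary", "neuropathy", "malignancy"), 0.0),
            "comparator": dict.fromkeys(
            ("cardiac", "liver", "renal", "pulmonary", "neuropathy", "malignancy"), 0.0)},
    )
    out = k.generate_outcomes(k.generate_persons(cfg, 1), cfg, 1)
    claims = k.generate_claims(out, cfg, 1)
    assert len(claims) == 0


def test_dataset_round_trip_and_regeneration(tmp_path, gen):
    cfg, _persons, anchor, claims = gen
    flags = k.generate_registry_flags(anchor)
    k.write_dataset(anchor, claims, tmp_path / "d1", flags, cfg, 7)
    back = k.read_dataset(tmp_path / "d1")
    assert len(back["persons"]) == len(anchor)
    got = back["claims"]
    pd.testing.assert_frame_equal(
        got, claims.reset_index(drop=True), check_dtype=False)
    # identical (config, seed) => byte-identical files
    k.write_dataset(anchor, claims, tmp_path / "d2", flags, cfg, 7)
    for name in ("persons.csv", "claims.csv", "manifest.json"):
        assert (tmp_path / "d1" / name).read_bytes() == \
               (tmp_path / "d2" / name).read_bytes()


def test_empty_claims_written_with_header_only(tmp_path, gen):
    cfg, _persons, anchor, claims = gen
    k.write_dataset(anchor, claims.iloc[:0], tmp_path / "e")
    lines = (tmp_path / "e" / "claims.csv").read_text().strip().splitlines()
    assert len(lines) == 1 and lines[0].startswith("patient_id,")


def test_fast_path_matches_claim_level_panel_moments():
    """Period-total fast path is distributionally equivalent to claims."""
    cfg = k.default_config(n_cases=3000, comparator_pool_size=0, trap_rate=0.0)
    out = k.generate_outcomes(k.generate_persons(cfg, 17), cfg, 17)
    claims = k.generate_claims(out, cfg, 18)
    cohort = pd.DataFrame({
        "patient_id": out["patient_id"], "role": "case",
        "index_date": pd.to_datetime(out["latent_index_date"]),
    })
    panel = k.build_panel(cohort, claims, out)
    fast = k.simulate_period_totals(out, cfg, 19)
    for col in ("cost_total", "visits_outpatient", "hospital_days"):
        a = panel.groupby("patient_id")[col].sum()
        b = fast.groupby("patient_id")[col].sum()
        # same population mean within 3 SE of the difference of means
        se = np.sqrt(a.var() / len(a) + b.var() / len(b))
        assert abs(a.mean() - b.mean()) < 3 * se


def test_expected_year1_cost_matches_analytic_expectation():
    """Simulated year-1 cost per case agrees with sum_p P(use)E[cost|use]."""
    cfg = k.default_config(n_cases=30_000, comparator_pool_size=0, trap_rate=0.0,
                           index_window=("2016-01-01", "2016-12-31"))
    out = k.generate_outcomes(k.generate_persons(cfg, 23), cfg, 23)
    fast = k.simulate_period_totals(out, cfg, 23)
    y1 = fast[fast["period"] <= 4].groupby("patient_id")["cost_total"].sum()
    # crude calibration: mean over entrants equals the printed target
    assert abs(y1.mean() - 294_490) / 294_490 < 0.02


def test_covariate_scores_center_near_zero(small_cfg):
    persons = k.generate_persons(
        small_cfg.with_(n_cases=5000, comparator_pool_size=0, trap_rate=0.0), 31)
    eta_u, eta_c = covariate_scores(small_cfg, persons)
    assert abs(np.mean(np.exp(eta_c))) < 1.5  # modest multiplicative spread
    assert np.isfinite(eta_u).all()
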