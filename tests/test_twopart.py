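import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

import kmsacost as k
from kmsacost.survival import KMCurve
from kmsacost.twopart import ContractError, TwoPartFit, fit_two_part_arrays


def const_X(pids):
    return pd.DataFrame({"const": 1.0},
                        index=pd.Index(pids, name="patient_id"))


def panel_cell(pids, y, role="case", period=1, component="cost_total",
               status="complete"):
    return pd.DataFrame({
        "patient_id": pids, "role": role, "period": period,
        "status": status, component: y,
    })


def test_intercept_only_two_part_closed_form():
    # 40% users with mean positive cost 1000 -> predicted mean 400
    y = np.array([0.0] * 60 + [1000.0] * 40)
    fit = fit_two_part_arrays(y, np.ones((100, 1)), ("const",),
                              "case", "cost_total", 1)
    assert fit.part1_prob == pytest.approx(0.4)
    assert fit.part2_mean == pytest.approx(1000.0)
    mu = k.recycled_predict(fit, const_X(["a", "b"]))
    assert mu == pytest.approx(400.0)


def test_structural_zero_period():
    fit = fit_two_part_arrays(np.zeros(50), np.ones((50, 1)), ("const",),
                              "case", "cost_total", 3)
    assert fit.structural_zero
    assert k.recycled_predict(fit, const_X(["a"])) == 0.0


def test_all_positive_records_probability_one():
    y = np.full(30, 250.0)
    X = np.column_stack([np.ones(30), np.linspace(0, 1, 30)])
    fit = fit_two_part_arrays(y, X, ("const", "x"), "case", "cost_total", 1)
    assert fit.part1_prob == 1.0


def test_too_few_positives_falls_back_to_intercept():
    y = np.zeros(100)
    y[:3] = [100.0, 150.0, 200.0]
    X = np.column_stack([np.ones(100), np.arange(100.0), np.arange(100.0) ** 2,
                         np.random.default_rng(0).random(100)])
    fit = fit_two_part_arrays(y, X, ("const", "a", "b", "c"),
                              "case", "cost_total", 1)
    assert fit.part2_params is None
    assert fit.part2_mean == pytest.approx(150.0)


def test_perfect_separation_falls_back_with_note():
    x = np.linspace(-1, 1, 60)
    y = np.where(x > 0, 100.0, 0.0)  # use perfectly separated on x
    X = np.column_stack([np.ones(60), x])
    fit = fit_two_part_arrays(y, X, ("const", "x"), "case", "cost_total", 1)
    assert fit.part1_params is None
    assert fit.part1_prob == pytest.approx(0.5)
    assert any("separation" in n for n in fit.notes)


def test_parameter_recovery_from_known_coefficients():
    """Logistic + gamma coefficients recovered within 3 SE at n = 20,000."""
    rng = np.random.default_rng(42)
    n = 20_000
    age = rng.normal(60, 14, n)
    male = rng.random(n) < 0.6
    cm = rng.random(n) < 0.25
    X = np.column_stack([np.ones(n), (age - 60) / 10, male, cm]).astype(float)
    b1 = np.array([0.3, 0.15, -0.2, 0.5])
    b2 = np.array([6.0, 0.08, 0.1, 0.3])
    use = rng.random(n) < expit(X @ b1)
    y = np.zeros(n)
    shape = 2.0
    y[use] = rng.gamma(shape, np.exp(X[use] @ b2) / shape)
    fit = fit_two_part_arrays(y, X, ("const", "age10", "male", "cm"),
                              "case", "cost_total", 1)
    # oracle SEs from direct statsmodels fits
    se1 = sm.GLM(use.astype(float), X, family=sm.families.Binomial()).fit().bse
    se2 = sm.GLM(y[use], X[use], family=sm.families.Gamma(
        link=sm.families.links.Log())).fit().bse
    assert np.all(np.abs(fit.part1_params - b1) < 3 * se1)
    assert np.all(np.abs(fit.part2_params - b2) < 3 * se2)


def test_recycled_prediction_null_model_is_half():
    fit = TwoPartFit("case", "cost_total", 1, ("const", "x"),
                     part1_params=np.zeros(2), part2_params=np.zeros(2))
    X = pd.DataFrame({"const": [1.0, 1.0], "x": [5.0, -3.0]})
    assert k.recycled_predict(fit, X) == pytest.approx(0.5)


def test_recycled_prediction_intercept_only_invariant_to_covariates():
    fit = TwoPartFit("case", "cost_total", 1, ("const", "x"),
                     part1_prob=0.3, part2_mean=200.0)
    Xa = pd.DataFrame({"const": [1.0] * 3, "x": [0.0, 1.0, 2.0]})
    Xb = pd.DataFrame({"const": [1.0] * 5, "x": [9.0] * 5})
    assert k.recycled_predict(fit, Xa) == k.recycled_predict(fit, Xb) == 60.0


def test_recycled_prediction_three_row_enumeration():
    a = np.array([0.1, 0.5])
    b = np.array([4.0, -0.2])
    fit = TwoPartFit("case", "cost_total", 1, ("const", "x"),
                     part1_params=a, part2_params=b)
    X = pd.DataFrame({"const": [1.0] * 3, "x": [0.0, 1.0, 2.0]})
    hand = np.mean([expit(a[0] + a[1] * x) * np.exp(b[0] + b[1] * x)
                    for x in (0.0, 1.0, 2.0)])
    assert k.recycled_predict(fit, X) == pytest.approx(hand, rel=1e-12)


def test_recycled_prediction_column_mismatch_raises():
    fit = TwoPartFit("case", "cost_total", 1, ("const", "x"), part1_prob=1.0,
                     part2_mean=1.0)
    with pytest.raises(ContractError):
        k.recycled_predict(fit, pd.DataFrame({"const": [1.0], "z": [0.0]}))


def two_period_setup(weight2=0.9, mu=(100.0, 200.0)):
    scheme = k.PeriodScheme(((0, 91), (91, 182)))
    curve = KMCurve(event_times=np.array([91.0]),
                    survival=np.array([weight2]),
                    n_risk=np.array([10]), n_event=np.array([1]),
                    max_observed=182.0)
    fits = {p + 1: TwoPartFit("case", "cost_total", p + 1, ("const",),
                              part1_prob=1.0, part2_mean=mu[p])
            for p in range(2)}
    return scheme, curve, fits


def test_kmsa_weighted_sum_hand_example():
    scheme, curve, fits = two_period_setup()
    est = k.kmsa_cumulative(fits, curve, const_X(["a"]), scheme, horizons=(182,))
    assert est.cumulative[182] == pytest.approx(100 + 0.9 * 200)


def test_kmsa_unit_survival_is_plain_sum():
    scheme, curve, fits = two_period_setup(weight2=1.0, mu=(50.0, 50.0))
    est = k.kmsa_cumulative(fits, curve, const_X(["a"]), scheme, horizons=(91, 182))
    assert est.cumulative[182] == pytest.approx(100.0)
    assert est.cumulative[91] == pytest.approx(50.0)


def test_kmsa_missing_period_fit_raises():
    scheme, curve, fits = two_period_setup()
    del fits[2]
    with pytest.raises(ContractError):
        k.kmsa_cumulative(fits, curve, const_X(["a"]), scheme, horizons=(182,))


def test_kmsa_horizon_monotonicity(bundle):
    est = bundle["kmsa_estimates"]
    per_cohort = est[est["cohort"].isin(("case", "comparator"))]
    for _key, g in per_cohort.groupby(["cohort", "component"]):
        vals = g.sort_values("horizon")["estimate"].to_numpy()
        assert vals[0] >= 0.0
        assert np.all(np.diff(vals) >= -1e-9)


def test_components_not_forced_to_sum_to_total(bundle):
    """Setting components are modeled separately from the total (by design)."""
    est = bundle["kmsa_estimates"]
    case3 = est[(est["cohort"] == "case") & (est["horizon"] == 1095)]
    vals = case3.set_index("component")["estimate"]
    parts = vals[["cost_outpatient", "cost_inpatient", "cost_emergency"]].sum()
    assert parts != pytest.approx(vals["cost_total"], rel=1e-6)


def test_incremental_cost_from_printed_cohort_means():
    # year-3 cumulative totals printed for the two cohorts
    diff = k.incremental_cost({1095: 597_873.0}, {1095: 148_230.0})
    assert diff[1095] == pytest.approx(449_643.0)


def test_incremental_equal_inputs_zero_and_mismatch_raises():
    assert k.incremental_cost({365: 5.0}, {365: 5.0})[365] == 0.0
    with pytest.raises(ContractError):
        k.incremental_cost({365: 1.0}, {730: 1.0})


def test_attenuation_higher_mortality_lowers_kmsa():
    """Scaling death hazards up strictly decreases the weighted cumulative."""
    scheme, _curve, fits = two_period_setup()
    lo = KMCurve(np.array([91.0]), np.array([0.9]), np.array([10]),
                 np.array([1]), 182.0)
    hi = KMCurve(np.array([91.0]), np.array([0.6]), np.array([10]),
                 np.array([4]), 182.0)
    X = const_X(["a"])
    e_lo = k.kmsa_cumulative(fits, lo, X, scheme, horizons=(182,))
    e_hi = k.kmsa_cumulative(fits, hi, X, scheme, horizons=(182,))
    assert e_hi.cumulative[182] < e_lo.cumulative[182]
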