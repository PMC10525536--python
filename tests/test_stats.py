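"""Repeatability statistics, Welch tests and the trial x donor model."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ivgp import ValidationError
from ivgp.stats import (
    cv_rf,
    fit_trial_donor_model,
    relative_difference,
    repeatability_report,
    unbiased_sd,
    welch_test,
)


def test_unbiased_sd_hand_values():
    assert unbiased_sd([5, 5, 5]) == 0.0
    assert unbiased_sd([1, 2, 3]) == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        unbiased_sd([1.0])


@given(st.lists(st.floats(-100, 100), min_size=2, max_size=30))
def test_unbiased_sd_matches_two_pass_oracle(values):
    x = np.asarray(values)
    mean = x.sum() / x.size
    oracle = np.sqrt(((x - mean) ** 2).sum() / (x.size - 1))
    assert unbiased_sd(values) == pytest.approx(oracle, rel=1e-12, abs=1e-12)


def test_cv_hand_values_and_scale_invariance():
    assert cv_rf([10, 10]) == 0.0
    assert cv_rf([1, 2, 3]) == pytest.approx(50.0)
    assert cv_rf([3, 6, 9]) == pytest.approx(cv_rf([1, 2, 3]), rel=1e-12)
    with pytest.raises(ValidationError):
        cv_rf([-1.0, 1.0])


def test_welch_identical_groups():
    res = welch_test([1, 2, 3], [1, 2, 3])
    assert res.t == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_welch_clear_separation():
    res = welch_test([1, 2, 3], [101.0, 101.9, 103.1])
    assert res.p < 1e-6


def test_welch_zero_variance_conventions():
    same = welch_test([5, 5], [5, 5, 5])
    assert same.t == 0.0 and same.p == 1.0
    diff = welch_test([5, 5], [6, 6])
    assert diff.p == 0.0


def test_welch_matches_textbook_formula_3v3():
    a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 9.0])
    res = welch_test(a, b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    t_hand = (a.mean() - b.mean()) / np.sqrt(va / 3 + vb / 3)
    df_hand = (va / 3 + vb / 3) ** 2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
    assert res.t == pytest.approx(t_hand, rel=1e-12)
    assert res.df == pytest.approx(df_hand, rel=1e-12)
    assert res.t == pytest.approx(-1.38873, abs=1e-5)
    assert res.df == pytest.approx(2.30588, abs=1e-5)


def _table(rft_vals, rfa_vals):
    rows = [
        {"trial_id": f"T{i}", "donor_type": "RF_T", "value": v}
        for i, v in enumerate(rft_vals)
    ] + [
        {"trial_id": f"A{i}", "donor_type": "RF_A", "value": v}
        for i, v in enumerate(rfa_vals)
    ]
    return pd.DataFrame(rows)


def test_nested_design_reduces_to_donor_effect():
    fit = fit_trial_donor_model(_table([1, 2, 3], [11, 12, 13]))
    assert any("rank deficient" in w for w in fit.warnings)
    assert fit.donor_p < 0.01
    assert fit.interaction_p is None


def test_identical_responses_reduce_to_intercept():
    fit = fit_trial_donor_model(_table([5.0] * 3, [5.0] * 4))
    assert fit.reduced_terms == []
    assert fit.donor_p is None or fit.donor_p >= 0.05


def test_crossed_design_interaction_detected_and_split():
    # trials 1-2 crossed with both donors, 3 replicates per cell; donor
    # effect present only in trial 2 -> strong interaction
    rng = np.random.default_rng(0)
    rows = []
    for trial in ("t1", "t2"):
        for donor in ("RF_T", "RF_A"):
            shift = 8.0 if (trial == "t2" and donor == "RF_A") else 0.0
            for _ in range(3):
                rows.append(
                    {"trial_id": trial, "donor_type": donor,
                     "value": 10.0 + shift + rng.normal(0, 0.3)}
                )
    fit = fit_trial_donor_model(pd.DataFrame(rows))
    assert fit.interaction_p is not None and fit.interaction_p < 0.05
    assert fit.split_trial_p is not None
    assert fit.split_trial_p["RF_A"] < 0.01  # trial effect within RF_A


def test_crossed_design_no_interaction_drops_it():
    rng = np.random.default_rng(1)
    rows = [
        {"trial_id": t, "donor_type": d, "value": 10.0 + (3.0 if d == "RF_A" else 0.0)
         + rng.normal(0, 0.3)}
        for t in ("t1", "t2", "t3")
        for d in ("RF_T", "RF_A")
        for _ in range(3)
    ]
    fit = fit_trial_donor_model(pd.DataFrame(rows))
    assert fit.interaction_p is not None and fit.interaction_p >= 0.05
    assert fit.donor_p < 1e-6


def test_repeatability_report_hand_values():
    per_trial = pd.DataFrame(
        [
            {"parameter": "x", "trial_id": "T1", "donor_type": "RF_T", "value": 1.0},
            {"parameter": "x", "trial_id": "T2", "donor_type": "RF_T", "value": 2.0},
            {"parameter": "x", "trial_id": "T3", "donor_type": "RF_T", "value": 3.0},
            {"parameter": "x", "trial_id": "A1", "donor_type": "RF_A", "value": 10.0},
            {"parameter": "x", "trial_id": "A2", "donor_type": "RF_A", "value": 10.0},
        ]
    )
    rep = repeatability_report(per_trial).iloc[0]
    assert rep["n_t"] == 3 and rep["n_a"] == 2
    assert rep["mean_t"] == pytest.approx(2.0)
    assert rep["cv_t"] == pytest.approx(50.0)
    assert rep["cv_a"] == pytest.approx(0.0)
    assert rep["sem_t"] == pytest.approx(1.0 / np.sqrt(3))
    # pooled-means CV uses all five trial values
    assert rep["cv_all_pooled_means"] == pytest.approx(cv_rf([1, 2, 3, 10, 10]))
    # within-type pooled SD: sqrt((2*1 + 1*0)/3) over grand mean 5.2
    assert rep["cv_all_within"] == pytest.approx(100 * np.sqrt(2 / 3) / 5.2)


def test_relative_difference_worked_examples():
    assert relative_difference(7.00, 5.90) == pytest.approx(18.6, abs=0.05)
    assert round(relative_difference(6.85, 6.71)) == 2
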