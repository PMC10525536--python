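"""Two-phase blank correction."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ivgp import BottleRun, ConfigurationError, ValidationError
from ivgp.blank import build_blank_profile, correct_sample

GRID5 = np.array([0.0, 10.0, 20.0, 30.0, 40.0])


def _blank_free(values, bid="blk"):
    # declining series are legal in-memory (the reader validates files, not arrays)
    return BottleRun(bid, "t", "blank", 0.0, GRID5[: len(values)],
                     np.asarray(values, dtype=float))


def _sample(values, bid="s", dm=0.5):
    return BottleRun(bid, "t", "sample", dm, GRID5[: len(values)],
                     np.asarray(values, dtype=float))


def test_mean_and_earliest_peak_of_two_blanks():
    prof = build_blank_profile([_blank_free([0, 2, 4, 3, 3]), _blank_free([0, 0, 2, 1, 1], "b2")], GRID5)
    np.testing.assert_allclose(prof.mean_cum_psi, [0, 1, 3, 2, 2])
    assert prof.peak_psi == 3.0
    assert prof.peak_time_min == 20.0


def test_constant_zero_blank_gives_zero_profile():
    prof = build_blank_profile([_blank_free([0, 0, 0, 0, 0])], GRID5)
    assert prof.peak_psi == 0.0
    assert prof.peak_time_min == 0.0  # earliest grid point on total tie


def test_identical_blanks_profile_equals_either():
    vals = [0.0, 1.5, 2.5, 2.0, 2.0]
    prof = build_blank_profile([_blank_free(vals), _blank_free(vals, "b2")], GRID5)
    np.testing.assert_allclose(prof.mean_cum_psi, vals)


def test_zero_blanks_is_a_configuration_error():
    with pytest.raises(ConfigurationError):
        build_blank_profile([], GRID5)


def test_two_phase_rule_hand_example():
    prof = build_blank_profile([_blank_free([0, 2, 4, 3, 3])], GRID5)
    corrected = correct_sample(_sample([0, 5, 10, 15, 20]), prof)
    # after the blank peak (4 at 20 min) the peak is subtracted: 15-4, 20-4
    np.testing.assert_allclose(corrected, [0, 3, 6, 11, 16])


def test_self_subtraction_and_zero_profile_identity():
    blank_vals = [0.0, 2.0, 4.0, 3.0, 3.0]
    prof = build_blank_profile([_blank_free(blank_vals)], GRID5)
    corrected = correct_sample(_sample(blank_vals), prof)
    np.testing.assert_allclose(corrected[:3], 0.0)
    assert (corrected[3:] <= 0).all()

    zero_prof = build_blank_profile([_blank_free([0, 0, 0, 0, 0])], GRID5)
    sample_vals = [0.0, 1.0, 4.0, 9.0, 9.5]
    np.testing.assert_allclose(correct_sample(_sample(sample_vals), zero_prof), sample_vals)


def test_short_sample_rejected():
    prof = build_blank_profile([_blank_free([0, 2, 4, 3, 3])], GRID5)
    with pytest.raises(ValidationError):
        correct_sample(_sample([0, 5, 10]), prof)


def test_phase_boundary_is_continuous():
    # at t = peak_time both formulas agree, so swapping the inequality
    # direction at the boundary must not change the result there
    prof = build_blank_profile([_blank_free([0, 2, 4, 3, 3])], GRID5)
    i = int(np.nonzero(prof.grid_min == prof.peak_time_min)[0][0])
    s = _sample([0, 5, 10, 15, 20])
    corrected = correct_sample(s, prof)
    assert corrected[i] == s.cum_pressure_psi[i] - prof.peak_psi
    assert corrected[i] == s.cum_pressure_psi[i] - prof.mean_cum_psi[i]


def test_monotone_sample_stays_monotone_after_peak():
    prof = build_blank_profile([_blank_free([0, 2, 4, 3, 3])], GRID5)
    corrected = correct_sample(_sample([0, 1, 2, 8, 9]), prof)
    assert (np.diff(corrected[2:]) >= 0).all()


@given(
    blank_vals=st.lists(st.floats(0, 50), min_size=5, max_size=5),
    sample_vals=st.lists(st.floats(0, 100), min_size=5, max_size=5),
)
def test_vectorized_rule_matches_per_point_oracle(blank_vals, sample_vals):
    sample_vals = np.sort(np.asarray(sample_vals))  # cumulative register
    prof = build_blank_profile([_blank_free(blank_vals)], GRID5)
    corrected = correct_sample(_sample(sample_vals.tolist()), prof)
    for i, t in enumerate(GRID5):
        if t <= prof.peak_time_min:
            expected = sample_vals[i] - prof.mean_cum_psi[i]
        else:
            expected = sample_vals[i] - prof.peak_psi
        assert corrected[i] == expected
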