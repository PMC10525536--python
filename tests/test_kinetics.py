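"""TGP interpolation, curve parameters and curve averaging."""
import numpy as np
import pytest

from ivgp import CurveModel, ValidationError
from ivgp.kinetics import average_curves, curve_parameters, tgp_at


def test_tgp_interpolation_and_bounds(make_curve):
    c = make_curve([0.0, 1.0, 2.0])  # grid 0, 10, 20 min
    assert tgp_at(c, 0.0) == 0.0
    assert tgp_at(c, 0.25) == pytest.approx(1.5)  # 15 min
    assert tgp_at(c, 1 / 6) == pytest.approx(1.0)  # exact grid hit
    with pytest.raises(ValidationError):
        tgp_at(c, 1.0)


def test_tgp_matches_closed_form_on_exponential_curve(make_curve):
    # A(1 - e^(-k t)) sampled every 10 min; interpolation error is bounded
    # by the curvature over one grid step: |V''| h^2 / 8
    A, k = 170.0, 0.25
    t_h = np.arange(0, 24 * 6 + 1) / 6.0
    c = make_curve(A * (1 - np.exp(-k * t_h)))
    h = 1 / 6
    bound = A * k**2 * h**2 / 8
    for hour in (0.05, 1.23, 7.77, 23.9):
        assert abs(tgp_at(c, hour) - A * (1 - np.exp(-k * hour))) <= bound


def test_linear_curve_parameters(make_curve):
    c = make_curve(np.arange(145) * 2.0)  # 2 mL per 10 min => 12 mL/h, 24 h span
    s = curve_parameters(c)
    assert s.Vmax == pytest.approx(12.0)
    assert s.Tmax_h == 0.0  # earliest tie
    assert s.H == pytest.approx(s.tgp_end / 2)
    assert s.H1_h == pytest.approx(12.0)  # linear: half volume at half time
    assert s.tgp_at_h[24.0] == pytest.approx(288.0)


def test_half_max_identity_and_degenerate_zero_curve(make_curve):
    z = curve_parameters(make_curve(np.zeros(145)))
    assert z.H == 0.0 and z.H1_h == 0.0 and z.Vmax == 0.0

    c = curve_parameters(make_curve(np.linspace(0, 169.58, 145)))
    assert c.H == pytest.approx(169.58 / 2, rel=1e-12)


def test_sigmoid_vmax_tmax_against_analytic(make_curve):
    model = CurveModel("sigmoid_monophasic", A=196.7, k=0.2226, t_half=11.81)
    t_h = np.arange(0, 24 * 6 + 1) / 6.0
    s = curve_parameters(make_curve(model.volume(t_h)))
    vmax_true, tmax_true = model.vmax_tmax(24.0)
    assert abs(s.Tmax_h - tmax_true) <= 1 / 6  # within one grid step
    assert s.Vmax == pytest.approx(vmax_true, rel=0.02)
    assert s.H1_h == pytest.approx(model.half_time(24.0), abs=0.02)


def test_vmax_tmax_match_brute_force_on_random_curves(make_curve):
    rng = np.random.default_rng(42)
    for _ in range(200):
        v = np.cumsum(rng.random(rng.integers(3, 30)))
        c = make_curve(v)
        s = curve_parameters(c)
        slopes = [
            (v[i + 1] - v[i]) / ((c.grid_min[i + 1] - c.grid_min[i]) / 60.0)
            for i in range(len(v) - 1)
        ]
        best = max(slopes)
        assert s.Vmax == best
        assert s.Tmax_h == c.grid_min[slopes.index(best)] / 60.0


def test_too_short_curve_rejected(make_curve):
    with pytest.raises(ValidationError):
        curve_parameters(make_curve([1.0]))
    with pytest.raises(ValidationError):
        curve_parameters(make_curve([0.0, 1.0, 2.0]), end_hour=24.0)


def test_average_curves(make_curve):
    one = make_curve([0.0, 2.0])
    mean, sem = average_curves([one])
    np.testing.assert_allclose(mean.ml_stp_per_g_dm, [0, 2])
    np.testing.assert_allclose(sem, 0.0)

    mean, sem = average_curves([make_curve([0.0, 2.0]), make_curve([0.0, 4.0])])
    np.testing.assert_allclose(mean.ml_stp_per_g_dm, [0, 3])
    with pytest.raises(ValidationError):
        average_curves([])


def test_mean_of_replicates_converges_to_truth(make_curve):
    # law of large numbers: SEM shrinks ~1/sqrt(N) and the mean approaches
    # the generating curve
    rng = np.random.default_rng(3)
    truth = np.linspace(0, 100, 20)
    curves_small = [make_curve(truth + rng.normal(0, 5, 20)) for _ in range(20)]
    curves_big = curves_small + [make_curve(truth + rng.normal(0, 5, 20)) for _ in range(180)]
    _, sem_small = average_curves(curves_small)
    mean_big, sem_big = average_curves(curves_big)
    assert sem_big[5:].mean() < sem_small[5:].mean() / 2  # ~sqrt(10) expected
    assert np.abs(mean_big.ml_stp_per_g_dm - truth).max() < 5 * 3 / np.sqrt(200) * 3
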