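"""Forward model: bell responses, baselines, predictors and their algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import glucotransfer as gt
from conftest import make_segment


def bell_oracle(alpha, amplitudes, taus, t):
    """Brute-force scalar evaluation of the superposed causal bell responses."""
    total = 0.0
    for h, tau in zip(amplitudes, taus):
        d = t - tau
        if d >= 0:
            total += h * math.exp(-0.5 * (d - 3 * alpha) ** 2 / alpha ** 2)
    return total


class TestBellResponse:
    def test_peak_value_at_three_alpha(self):
        out = gt.bell_response(10.0, [5.0], [0.0], np.array([30.0]))
        assert out[0] == pytest.approx(5.0, abs=1e-12)

    def test_frozen_scalar_value(self):
        # one event, evaluated off-peak: 5 * exp(-0.5)
        out = gt.bell_response(10.0, [5.0], [0.0], np.array([20.0]))
        assert out[0] == pytest.approx(3.0326532985631671, rel=1e-12)

    def test_no_events_gives_zero_series(self):
        grid = np.arange(0, 90, 5.0)
        np.testing.assert_array_equal(gt.bell_response(10.0, [], [], grid), 0.0)

    def test_causality(self):
        out = gt.bell_response(10.0, [5.0], [50.0], np.array([0.0, 45.0, 49.9]))
        np.testing.assert_array_equal(out, 0.0)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            gt.bell_response(0.0, [1.0], [0.0], np.array([1.0]))

    def test_matches_oracle_on_random_cases(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(1, 4)
            alpha = rng.uniform(2, 30)
            h = rng.normal(0, 3, n)
            tau = rng.uniform(0, 120, n)
            grid = rng.uniform(-10, 200, 6)
            out = gt.bell_response(alpha, h, tau, grid)
            expect = [bell_oracle(alpha, h, tau, t) for t in grid]
            np.testing.assert_allclose(out, expect, rtol=1e-9, atol=1e-12)

    def test_peak_location_and_height(self):
        # each term's maximum sits at tau + 3*alpha with height h
        alpha, h, tau = 7.0, 4.2, 13.0
        dense = np.linspace(0, 200, 4001)
        out = gt.bell_response(alpha, [h], [tau], dense)
        assert abs(dense[np.argmax(out)] - (tau + 3 * alpha)) <= dense[1] - dense[0]
        assert out.max() == pytest.approx(h, rel=1e-9)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(alpha=st.floats(2.0, 30.0),
           h1=st.floats(-3, 3), h2=st.floats(-3, 3),
           t1=st.floats(0, 100), t2=st.floats(0, 100))
    def test_superposition(self, alpha, h1, h2, t1, t2):
        grid = np.linspace(-5, 150, 40)
        both = gt.bell_response(alpha, [h1, h2], [t1, t2], grid)
        parts = (gt.bell_response(alpha, [h1], [t1], grid)
                 + gt.bell_response(alpha, [h2], [t2], grid))
        np.testing.assert_allclose(both, parts, rtol=1e-12, atol=1e-12)


class TestBaseline:
    def test_even_count_median(self):
        seg = make_segment(pre=[5.0, 5.2, 5.4, 6.0])
        assert gt.baseline_glucose(seg) == pytest.approx(5.3)

    def test_constant_pre_window(self):
        seg = make_segment(pre=[6.1, 6.1, 6.1, 6.1])
        assert gt.baseline_glucose(seg) == pytest.approx(6.1)


class TestResponses:
    def test_dietary_two_meal_frozen_value(self, params):
        # 30 g at t=0 and 40 g at t=60, alpha_d=10, beta_d=0.1, at t=70:
        # 3*exp(-8) + 4*exp(-2)
        seg = make_segment(meal_time=0, carbs=30.0)
        seg.meals_in_window.append(gt.MealEvent(60, 40.0))
        p = gt.PersonParams(alpha_d=10.0, beta_d=0.1)
        out = gt.dietary_response(p, seg, grid=np.array([70.0]))
        assert out[0] == pytest.approx(3 * math.exp(-8) + 4 * math.exp(-2), rel=1e-12)

    def test_dietary_linearity_in_dose(self, params):
        seg1 = make_segment(carbs=25.0)
        seg2 = make_segment(carbs=50.0)
        r1 = gt.dietary_response(params, seg1)
        r2 = gt.dietary_response(params, seg2)
        np.testing.assert_allclose(r2, 2.0 * r1, rtol=1e-12)

    def test_zero_carbs_zero_response(self, params):
        seg = make_segment(carbs=0.0)
        np.testing.assert_array_equal(gt.dietary_response(params, seg), 0.0)

    def test_exercise_frozen_value(self):
        # beta_e=-0.02, z=100, alpha_e=8, delta=16: -2*exp(-0.5)
        seg = make_segment(exercises=[(780, 100.0)])
        p = gt.PersonParams(alpha_d=10, beta_d=0.04, alpha_e=8.0, beta_e=-0.02)
        out = gt.exercise_response(p, seg, grid=np.array([796.0]))
        assert out[0] == pytest.approx(-2 * math.exp(-0.5), rel=1e-12)

    def test_no_exercise_zero_series(self, params):
        seg = make_segment()
        np.testing.assert_array_equal(gt.exercise_response(params, seg), 0.0)


class TestPredict:
    def test_component_sum_identity(self, params):
        seg = make_segment(exercises=[(780, 90.0)])
        traj = gt.predict("synergistic", params, seg)
        np.testing.assert_allclose(
            traj.y_hat, traj.y_base + traj.r_d + traj.r_e + traj.synergy,
            rtol=0, atol=1e-12)

    def test_hand_arithmetic_point(self):
        # y_base 5.3, R_d 2.0, R_e -1.0, C 0.3 -> 5.3 + 2 - 1 + 0.3*(-2) = 5.7
        assert 5.3 + 2.0 - 1.0 + 0.3 * (2.0 * -1.0) == pytest.approx(5.7)
        seg = make_segment(pre=[5.3, 5.3, 5.3, 5.3], carbs=50.0,
                           exercises=[(780, 100.0)])
        p = gt.PersonParams(alpha_d=12, beta_d=0.04, alpha_e=10, beta_e=-0.01,
                            c_syn=0.3)
        traj = gt.predict("synergistic", p, seg)
        i = 5
        expect = (traj.y_base + traj.r_d[i] + traj.r_e[i]
                  + 0.3 * traj.r_d[i] * traj.r_e[i])
        assert traj.y_hat[i] == pytest.approx(expect, rel=1e-12)

    def test_nesting_c_zero_equals_additive(self, params):
        rng = np.random.default_rng(3)
        for _ in range(50):
            seg = make_segment(carbs=float(rng.uniform(10, 90)),
                               exercises=[(int(750 + 5 * rng.integers(1, 12)),
                                           float(rng.uniform(5, 150)))])
            p = gt.PersonParams(alpha_d=float(rng.uniform(5, 25)),
                                beta_d=float(rng.uniform(0.01, 0.08)),
                                alpha_e=float(rng.uniform(5, 20)),
                                beta_e=float(rng.uniform(-0.05, 0.0)),
                                c_syn=0.0)
            syn = gt.predict("synergistic", p, seg)
            add = gt.predict("additive", p, seg)
            np.testing.assert_array_equal(syn.y_hat, add.y_hat)

    def test_nesting_no_exercise_equals_single(self, params):
        seg = make_segment()  # no exercise events
        add = gt.predict("additive", params, seg)
        single = gt.predict("single", params, seg)
        np.testing.assert_array_equal(add.y_hat, single.y_hat)

    def test_unknown_model_kind(self, params, segment):
        with pytest.raises(ValueError):
            gt.predict("quadratic", params, segment)
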