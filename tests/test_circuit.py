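"""Circuit dynamics: steady states, exact adaptation, fold-change detection."""

import numpy as np
import pytest

from rewardtaxis.circuit import (
    MOUSE,
    PRIMATE,
    CircuitParams,
    make_propagator,
    quasi_static_output,
    response_amplitude,
    reward_response_after_adaptation,
    simulate,
    steady_state,
)
from rewardtaxis.fields import RewardSignal, make_step


def grid(t_end=10.0, dt=0.001):
    return np.arange(0.0, t_end + 0.5 * dt, dt)


class TestSteadyState:
    def test_mouse_baseline_levels(self):
        st = steady_state(MOUSE, 1.0)
        assert st.d == pytest.approx(5.0)
        assert st.g == pytest.approx((15 - 5 + 6 * 0) / 0.7)

    def test_g_tracks_log_input(self):
        st = steady_state(MOUSE, np.e)
        assert st.g == pytest.approx((15 - 5 + 6 * 1) / 0.7)

    @pytest.mark.parametrize("variant", ["feedback", "feedforward", "quasi_static", "rectified"])
    @pytest.mark.parametrize("R0", [0.01, 1.0, 37.5])
    def test_exact_adaptation_fixed_point(self, variant, R0):
        params = MOUSE.with_variant(variant)
        assert steady_state(params, R0).d == pytest.approx(params.d0)

    def test_feedforward_closed_form(self):
        st = steady_state(MOUSE.with_variant("feedforward"), np.e)
        assert st.g == pytest.approx((15 + 6) / 0.7)

    def test_rejects_nonpositive_reward(self):
        with pytest.raises(ValueError):
            steady_state(MOUSE, 0.0)
        with pytest.raises(ValueError):
            steady_state(MOUSE, -2.0)


class TestQuasiStaticOutput:
    def test_direct_evaluation(self):
        assert quasi_static_output(MOUSE, 1.0, 0.0) == pytest.approx(15.0)
        assert quasi_static_output(MOUSE, np.exp(2.0), 10.0) == pytest.approx(15 + 12 - 7)

    def test_adapted_g_returns_baseline(self):
        g = steady_state(MOUSE, 3.0).g
        assert quasi_static_output(MOUSE, 3.0, g) == pytest.approx(MOUSE.d0)

    def test_rectified_clips_at_zero(self):
        params = MOUSE.with_variant("rectified", k_d=1.0)
        assert quasi_static_output(params, 1e-6, 30.0) == 0.0


class TestSimulate:
    def test_constant_input_stays_at_baseline(self):
        sig = RewardSignal(lambda t: np.full_like(np.asarray(t, float), 3.0))
        trace = simulate(MOUSE, sig, grid(2.0))
        assert np.max(np.abs(trace.d_series - 5.0)) < 1e-6

    @pytest.mark.parametrize("params", [MOUSE, PRIMATE])
    def test_step_adapts_exactly_and_g_settles(self, params):
        trace = simulate(params, make_step(1.0, 7.0, 1.0), grid(10.0))
        assert trace.d_series[-1] == pytest.approx(params.d0, rel=1e-6)
        g_expected = (params.C - params.d0 + params.mu * np.log(8.0)) / params.alpha
        assert trace.g_series[-1] == pytest.approx(g_expected, rel=1e-4)

    @pytest.mark.parametrize("variant", ["feedback", "feedforward"])
    @pytest.mark.parametrize("lam", [0.1, 10.0, 100.0])
    def test_fcd_invariance_on_step(self, variant, lam):
        params = MOUSE.with_variant(variant)
        sig = make_step(1.0, 7.0, 1.0)
        t = grid(5.0)
        base = simulate(params, sig, t)
        scaled = simulate(params, sig.scaled(lam), t)
        assert np.max(np.abs(base.d_series - scaled.d_series)) < 1e-6

    def test_rejects_nonpositive_signal_and_bad_grid(self):
        with pytest.raises(ValueError):
            simulate(MOUSE, RewardSignal(lambda t: np.asarray(t, float) - 10.0), grid(2.0))
        with pytest.raises(ValueError):
            simulate(MOUSE, make_step(1.0, 7.0, 1.0), np.array([0.0, 2.0, 1.0]))

    def test_rectified_never_negative_on_omission(self):
        # omission-like drop drives the unrectified model negative;
        # the rectified variant clamps at zero along the whole trajectory
        sig = make_step(7.0, -6.0, 1.0)
        t = grid(5.0)
        base = simulate(MOUSE, sig, t)
        assert base.d_series.min() < 0  # acknowledged limitation of the linear model
        for k_d in (1.0, 0.1, 0.01):
            rect = simulate(MOUSE.with_variant("rectified", k_d=k_d), sig, t)
            assert np.all(rect.d_series >= 0.0)

    @pytest.mark.parametrize("k_d", [1.0, 0.1, 0.01])
    def test_rectified_reduces_to_fcd_model_when_unclamped(self, k_d):
        # on an upward step d stays positive and the rectified model is the
        # quasi-static FCD model exactly (the k_d offset is absorbed by the
        # adapted GABAergic level), for every k_d << d0
        sig = make_step(1.0, 7.0, 1.0)
        t = grid(5.0)
        qs = simulate(MOUSE.with_variant("quasi_static"), sig, t)
        rect = simulate(MOUSE.with_variant("rectified", k_d=k_d), sig, t)
        assert np.max(np.abs(rect.d_series - qs.d_series)) < 1e-6
        # and the quasi-static trace itself tracks the full two-ODE model up
        # to the timescale-separation error after the fast transient
        base = simulate(MOUSE, sig, t)
        mask = t >= 1.5
        assert np.max(np.abs(qs.d_series[mask] - base.d_series[mask])) < 0.3

    def test_step_halving_convergence(self):
        sig = make_step(1.0, 7.0, 0.5)
        coarse = simulate(MOUSE, sig, grid(3.0, 0.002))
        fine = simulate(MOUSE, sig, grid(3.0, 0.001))
        assert np.max(np.abs(coarse.d_series - fine.d_series[::2])) < 1e-6


class TestResponseAmplitude:
    def test_flat_trace_is_zero(self):
        sig = RewardSignal(lambda t: np.ones_like(np.asarray(t, float)))
        trace = simulate(MOUSE, sig, grid(2.0))
        assert response_amplitude(trace, (0.0, 2.0)) == pytest.approx(0.0, abs=1e-9)

    def test_equal_fold_changes_give_equal_amplitudes(self):
        t = grid(4.0)
        a1 = response_amplitude(simulate(MOUSE, make_step(1.0, 7.0, 1.0), t), (1.0, 4.0))
        a2 = response_amplitude(simulate(MOUSE, make_step(2.0, 14.0, 1.0), t), (1.0, 4.0))
        assert a1 > 0
        assert a1 == pytest.approx(a2, rel=1e-6)

    def test_amplitude_matches_fine_reference(self):
        sig = make_step(1.0, 7.0, 1.0)
        a_coarse = response_amplitude(simulate(MOUSE, sig, grid(4.0, 0.001)), (1.0, 4.0))
        a_fine = response_amplitude(simulate(MOUSE, sig, grid(4.0, 0.0001)), (1.0, 4.0))
        assert a_coarse == pytest.approx(a_fine, rel=1e-4)

    def test_empty_window_rejected(self):
        sig = RewardSignal(lambda t: np.ones_like(np.asarray(t, float)))
        trace = simulate(MOUSE, sig, grid(2.0))
        with pytest.raises(ValueError):
            response_amplitude(trace, (5.0, 6.0))


class TestRewardResponseAfterAdaptation:
    def test_fulfilled_prediction_gives_zero(self):
        assert reward_response_after_adaptation(MOUSE, 2.0, 0.0, 2.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("scale", [1.0, 10.0, 1000.0])
    def test_twofold_change_is_scale_invariant(self, scale):
        resp = reward_response_after_adaptation(MOUSE, 0.5 * scale, 0.0, 1.0 * scale)
        assert resp == pytest.approx(6 * np.log(2.0))

    def test_omission_like_negative_response(self):
        resp = reward_response_after_adaptation(MOUSE, 4.0, 0.0, 2.0)
        assert resp == pytest.approx(6 * np.log(0.5))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            reward_response_after_adaptation(MOUSE, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            reward_response_after_adaptation(MOUSE, 1.0, 0.0, 0.0)


class TestParams:
    def test_invalid_params_rejected(self):
        for kwargs in ({"omega_d": -1.0}, {"alpha": 0.0}, {"d0": 0.0}, {"variant": "bogus"}):
            with pytest.raises(ValueError):
                CircuitParams(**kwargs)

    def test_slow_dopamine_warns(self):
        with pytest.warns(UserWarning):
            CircuitParams(omega_d=10.0, omega=15.0)


class TestPropagator:
    """The piecewise-constant-input propagator must agree with the ODE solver."""

    @pytest.mark.parametrize("variant", ["feedback", "feedforward", "quasi_static", "rectified"])
    def test_matches_simulate_on_step_input(self, variant):
        params = MOUSE.with_variant(variant)
        sig = make_step(1.0, 7.0, 0.2)
        dt = 0.001
        t = grid(2.0, dt)
        ref = simulate(params, sig, t)
        step = make_propagator(params, dt)
        d = np.array([ref.d_series[0]])
        g = np.array([ref.g_series[0]])
        for ti in t[:-1]:
            logR = np.log(sig(ti + dt))
            d, g = step(d, g, np.array([logR]))
        assert d[0] == pytest.approx(ref.d_series[-1], abs=2e-3)
        assert g[0] == pytest.approx(ref.g_series[-1], abs=2e-3)
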