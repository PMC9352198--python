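"""Reward signals and spatial fields: positivity, log-gradients, fold changes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rewardtaxis.fields import (
    CueRewardSchedule,
    DiscountedValueSpec,
    ExpDecayField,
    GaussianMixtureField,
    LogLinearField,
    UniformField,
    delay_fold_ratio,
    expected_reward_at_delay,
    make_cue_reward,
    make_expdecay_field,
    make_gaussian_field,
    make_shifted_pair_schedule,
    make_step,
    parse_field_spec,
    parse_signal_spec,
)


class TestStepSignal:
    def test_levels_around_discontinuity(self):
        sig = make_step(1.0, 7.0, 1.0)
        assert sig(0.5) == 1.0
        assert sig(1.5) == 8.0
        assert sig.discontinuities == (1.0,)

    def test_zero_lambda_is_constant(self):
        sig = make_step(1.0, 0.0, 1.0)
        assert np.all(sig(np.linspace(0, 5, 11)) == 1.0)

    def test_omission_like_downstep(self):
        sig = make_step(7.0, -6.0, 1.0)
        assert sig(0.0) == 7.0
        assert sig(2.0) == 1.0

    def test_nonpositive_poststep_rejected(self):
        with pytest.raises(ValueError):
            make_step(1.0, -1.0, 0.0)
        with pytest.raises(ValueError):
            make_step(0.0, 1.0, 0.0)


class TestCueReward:
    def test_levels_small_reward(self):
        s = CueRewardSchedule(u=0.05, p=0.5, b=2.0, lam=10.0)
        assert s.cue_level == pytest.approx(1.25)
        assert s.reward_level == pytest.approx(2.5)
        assert s.fold_change_at_delivery == pytest.approx(2.0)

    @pytest.mark.parametrize("u", [0.05, 0.15, 0.5, 3.7])
    def test_fold_change_is_1_over_p_for_any_magnitude(self, u):
        s = CueRewardSchedule(u=u, p=0.5, b=2.0, lam=10.0)
        assert s.fold_change_at_delivery == pytest.approx(1.0 / s.p)

    def test_certain_reward_has_unit_fold_change(self):
        s = CueRewardSchedule(u=0.5, p=1.0)
        assert s.fold_change_at_delivery == pytest.approx(1.0)

    def test_signal_time_course_delivery_and_omission(self):
        s = CueRewardSchedule(u=0.5, p=0.5, b=2.0, lam=10.0, t_cue=1.0, t_reward=2.0)
        sig = make_cue_reward(s)
        assert sig(0.5) == s.R_pre
        assert sig(1.5) == pytest.approx(3.5)
        assert sig(2.5) == pytest.approx(7.0)
        omit = make_cue_reward(CueRewardSchedule(u=0.5, delivered=False))
        assert omit(2.5) == s.R_pre

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            CueRewardSchedule(u=0.5, p=0.0)


class TestExpectedRewardAtDelay:
    def test_direct_evaluation(self):
        assert expected_reward_at_delay(10.0, 0.5, 0.99, 10) == pytest.approx(0.5 * 0.99**10 * 10)

    def test_fold_ratio_independent_of_magnitude(self):
        assert delay_fold_ratio(0.5, 1.0, 10) == pytest.approx(2.0)
        assert delay_fold_ratio(1.0, 1.0, 3) == pytest.approx(1.0)


FIELDS = [
    GaussianMixtureField(R1=4.0, R2=1.0, x1=30.0, x2=-30.0, b=10.0),
    GaussianMixtureField(R1=0.5, R2=8.0, x1=10.0, x2=-25.0, b=7.0, asymmetric=True),
    ExpDecayField(0.04, 1.5),
    LogLinearField(0.02),
]


class TestFieldGradients:
    @pytest.mark.parametrize("field", FIELDS, ids=lambda f: type(f).__name__)
    def test_analytic_grad_matches_central_difference(self, field):
        rng = np.random.default_rng(7)
        x = rng.uniform(1.0, 60.0, size=50)  # positive so ExpDecay is in-domain
        h = 1e-6
        numeric = (field.log_value(x + h) - field.log_value(x - h)) / (2 * h)
        assert np.allclose(field.grad_log(x), numeric, rtol=1e-5, atol=1e-7)

    @pytest.mark.parametrize("field", FIELDS, ids=lambda f: type(f).__name__)
    def test_positive_everywhere(self, field):
        x = np.linspace(0.0, 90.0, 200)
        assert np.all(field.value(x) > 0)

    def test_far_tails_do_not_underflow_logs(self):
        field = GaussianMixtureField(R1=4.0, R2=1.0)
        assert np.isfinite(field.log_value(np.array([-500.0, 500.0]))).all()


class TestGaussianMixture:
    def test_peak_value_dominated_by_near_peak(self):
        f = make_gaussian_field(4.0, 1.0, 30.0, -30.0, 10.0)
        assert f.value(30.0) == pytest.approx(4.0, rel=1e-3)
        assert abs(f.grad_log(-30.0)) < 1e-3  # local maximum

    def test_midpoint_direct_evaluation(self):
        f = make_gaussian_field(4.0, 1.0, 30.0, -30.0, 10.0)
        expected = 4.0 * np.exp(-0.5 * 9.0) + 1.0 * np.exp(-0.5 * 9.0)
        assert f.value(0.0) == pytest.approx(expected)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GaussianMixtureField(R1=-1.0, R2=1.0)
        with pytest.raises(ValueError):
            GaussianMixtureField(b=0.0)


class TestExpDecayField:
    def test_values_and_log_slope(self):
        f = make_expdecay_field()
        assert f.value(0.0) == pytest.approx(1.0)
        assert f.value(1.0) == pytest.approx(np.exp(-0.04))
        assert f.grad_log(1.0) == pytest.approx(-0.06)

    def test_negative_position_rejected(self):
        with pytest.raises(ValueError):
            make_expdecay_field().value(-1.0)


class TestShiftedPairSchedule:
    def test_magnitudes(self):
        mags, signals = make_shifted_pair_schedule(1.0, 0.5, n_trials=50, seed=0)
        assert set(np.unique(mags)) == {0.5, 1.5}
        assert len(signals) == 50

    def test_large_mean_magnitudes(self):
        mags, _ = make_shifted_pair_schedule(11.0, 0.5, n_trials=20, seed=0)
        assert set(np.unique(mags)) <= {10.5, 11.5}

    def test_delivery_fold_shrinks_with_mean(self):
        # expected reward steps X -> X+Y at delivery: the fold change
        # (X+Y)/X shrinks as X grows, so an FCD circuit responds less
        _, sig_small = make_shifted_pair_schedule(1.0, 0.5, n_trials=1, seed=1)
        _, sig_large = make_shifted_pair_schedule(11.0, 0.5, n_trials=1, seed=1)
        fold_small = sig_small[0](10.0) / sig_small[0](1.5)
        fold_large = sig_large[0](10.0) / sig_large[0](1.5)
        assert abs(np.log(fold_small)) > abs(np.log(fold_large))

    def test_requires_positive_magnitudes(self):
        with pytest.raises(ValueError):
            make_shifted_pair_schedule(0.5, 0.5)


class TestDiscountedValue:
    def test_explicit_sum(self):
        spec = DiscountedValueSpec(0.9, rewards=(0.0, 0.0, 10.0))
        assert spec.value() == pytest.approx(0.81 * 10.0)


class TestSpecParsing:
    def test_signal_specs(self):
        sig = parse_signal_spec("step:1,7,1")
        assert sig(2.0) == 8.0
        cue = parse_signal_spec("cue_reward:0.5,0.5,2,10,1,2")
        assert cue(1.5) == pytest.approx(3.5)

    def test_field_specs(self):
        f = parse_field_spec("gauss2:4,1,30,-30,10")
        assert isinstance(f, GaussianMixtureField)
        assert isinstance(parse_field_spec("expdecay:0.04,1.5"), ExpDecayField)
        assert isinstance(parse_field_spec("uniform:2"), UniformField)
        with pytest.raises(ValueError):
            parse_field_spec("nope:1")


@settings(max_examples=50, deadline=None)
@given(
    R0=st.floats(0.01, 100.0),
    lam_scale=st.floats(0.1, 100.0),
    t=st.floats(0.0, 10.0),
)
def test_signals_stay_positive_under_scaling(R0, lam_scale, t):
    sig = make_step(R0, 3 * R0, 1.0).scaled(lam_scale)
    assert sig(t) > 0
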