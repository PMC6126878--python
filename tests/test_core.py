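"""Unit and property tests for the module equations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rml import ModelParams
from rml.core import (
    RateFilterState,
    action_preferences,
    compute_da_act,
    compute_da_boost,
    softmax_policy,
    update_rate_filter,
    update_value,
)

finite_floats = st.floats(
    min_value=-50, max_value=50, allow_nan=False, allow_infinity=False
)


class TestSoftmaxPolicy:
    @pytest.mark.parametrize(
        "values, tau, expected",
        [
            ((0.0, 0.0), 0.6, (0.5, 0.5)),
            ((3.7, 3.7, 3.7), 1.3, (1 / 3, 1 / 3, 1 / 3)),
            # direct evaluation of exp(x/tau) normalisation
            ((0.6, 0.0), 0.6, (math.e / (math.e + 1), 1 / (math.e + 1))),
        ],
    )
    def test_examples(self, values, tau, expected):
        np.testing.assert_allclose(softmax_policy(np.array(values), tau), expected, atol=1e-12)

    @given(st.lists(finite_floats, min_size=1, max_size=8), st.floats(0.05, 5.0))
    @settings(max_examples=200, deadline=None)
    def test_is_distribution_and_order_preserving(self, values, tau):
        p = softmax_policy(np.array(values), tau)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-9
        order = np.argsort(values, kind="stable")
        assert np.all(np.diff(p[order]) >= -1e-12)

    @given(st.lists(finite_floats, min_size=1, max_size=8), st.floats(0.05, 5.0), finite_floats)
    @settings(max_examples=200, deadline=None)
    def test_translation_invariance(self, values, tau, shift):
        a = softmax_policy(np.array(values), tau)
        b = softmax_policy(np.array(values) + shift, tau)
        np.testing.assert_allclose(a, b, atol=1e-9)

    @pytest.mark.parametrize(
        "values, tau",
        [((0.0, 1.0), 0.0), ((0.0, 1.0), -1.0), ((np.nan, 1.0), 0.6), ((np.inf, 0.0), 0.6)],
    )
    def test_invalid_inputs_rejected(self, values, tau):
        with pytest.raises(ValueError):
            softmax_policy(np.array(values), tau)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            softmax_policy(np.array([]), 0.6)


class TestActionPreferences:
    def test_zero_cost_identity(self):
        v = np.array([0.3, -0.2, 0.0])
        np.testing.assert_array_equal(action_preferences(v, np.zeros(3), ne=4.0), v)

    def test_norepinephrine_discounts_cost(self):
        # high NE makes an effortful action attractive...
        assert action_preferences(np.array([0.8]), np.array([2.0]), ne=10.0)[0] == pytest.approx(0.6)
        # ...low NE makes it unattractive
        assert action_preferences(np.array([0.5]), np.array([2.0]), ne=1.0)[0] == pytest.approx(-1.5)

    def test_dacc_gain_scales_values_not_costs(self):
        pref = action_preferences(np.array([0.8]), np.array([1.0]), ne=2.0, dacc_gain=0.5)
        assert pref[0] == pytest.approx(0.5 * 0.8 - 1.0 / 2.0)

    def test_low_ne_rejected(self):
        with pytest.raises(ValueError):
            action_preferences(np.array([0.5]), np.array([0.0]), ne=0.5)


class TestUpdateValue:
    def test_hand_example(self):
        new, pe = update_value(0.0, 1.0, lam=0.2, beta=0.2)
        assert new == pytest.approx(0.2)
        assert pe == pytest.approx(1.0)

    def test_zero_prediction_error_is_fixed_point(self):
        new, pe = update_value(0.7, 0.7, lam=0.5, beta=0.2)
        assert new == 0.7 and pe == 0.0

    def test_full_update_limit(self):
        new, _ = update_value(-3.0, 1.25, lam=1.0, beta=0.2)
        assert new == 1.25

    @pytest.mark.parametrize("lam", [0.1, 1.5, -0.2])
    def test_rate_outside_bounds_rejected(self, lam):
        with pytest.raises(ValueError):
            update_value(0.0, 1.0, lam=lam, beta=0.2)

    def test_geometric_error_decay_to_constant_target(self):
        # with constant teaching signal T and constant lam, |v - T| shrinks
        # by exactly (1 - lam) per step
        v, T, lam = 0.0, 2.0, 0.3
        err = abs(v - T)
        for _ in range(40):
            v, _ = update_value(v, T, lam, beta=0.2)
            assert abs(v - T) == pytest.approx((1 - lam) * err, rel=1e-12)
            err = abs(v - T)
        assert err < 1e-5


class TestRateFilter:
    def test_hand_example(self):
        state = RateFilterState(v_hat=0.0, delta_hat=0.5, lam=0.2)
        new = update_rate_filter(state, v_now=1.0, delta_now=1.0, alpha=0.3, beta=0.2)
        assert new.v_hat == pytest.approx(0.3)
        assert new.delta_hat == pytest.approx(0.65)
        # var = (1 - 0)^2 = 1; lam = min(1, 1 / 0.65^2) = 1
        assert new.lam == 1.0

    def test_stationary_limit_hits_floor(self):
        state = RateFilterState.initial(beta=0.2)
        for _ in range(200):
            state = update_rate_filter(state, v_now=0.8, delta_now=0.0, alpha=0.3, beta=0.2)
        assert state.lam == 0.2

    def test_zero_delta_hat_never_divides(self):
        fresh = RateFilterState(v_hat=0.0, delta_hat=0.0, lam=0.2)
        # var > 0 with zero delta_hat -> lam clamps to 1
        assert update_rate_filter(fresh, 1.0, 0.0, 0.3, 0.2).lam == 1.0
        # var == 0 with zero delta_hat -> lam at the floor
        assert update_rate_filter(fresh, 0.0, 0.0, 0.3, 0.2).lam == 0.2

    @given(
        st.lists(st.tuples(finite_floats, finite_floats), min_size=1, max_size=60),
        st.floats(0.05, 0.95),
        st.floats(0.05, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_lam_always_within_bounds(self, steps, alpha, beta):
        state = RateFilterState.initial(beta)
        for v_now, delta_now in steps:
            state = update_rate_filter(state, v_now, delta_now, alpha, beta)
            assert beta <= state.lam <= 1.0
            assert state.delta_hat >= 0.0

    def test_changepoint_raises_rate_above_stationary(self):
        """Oracle simulation: a delta-rule tracker driven by the filter shows
        higher mean lam after an abrupt mean shift than in matched
        stationary noise of the same total variance."""
        alpha, beta = 0.3, 0.2
        n, shift_at = 1000, 500
        stat_lams, vol_lams = [], []
        for seed in range(50):
            g = np.random.default_rng(seed)
            noise = g.normal(0.0, 0.5, size=n)
            for shifted in (False, True):
                x = noise.copy()
                if shifted:
                    x[shift_at:] += 2.0
                v, state = 0.0, RateFilterState.initial(beta)
                lams = []
                for t in range(n):
                    pe = x[t] - v
                    state = update_rate_filter(state, v, pe, alpha, beta)
                    v += state.lam * pe
                    lams.append(state.lam)
                window = np.mean(lams[shift_at : shift_at + 50])
                (vol_lams if shifted else stat_lams).append(window)
        assert np.mean(vol_lams) > np.mean(stat_lams)


class TestVtaSignals:
    def test_da_act_hand_examples(self, params):
        assert compute_da_act(1, 1.0, 1, 0.0, params) == pytest.approx(1.1)
        assert compute_da_act(0, 0.0, 3, 0.0, params) == 0.0

    def test_da_act_mu_zero_reduces_to_q_learning_target(self):
        p = ModelParams(mu=0.0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            r = int(rng.integers(0, 2))
            R, nxt = rng.uniform(0, 2), rng.uniform(0, 2)
            da = compute_da_act(r, R, b=1, max_next_v=nxt, params=p)
            assert da == pytest.approx(r * R + p.rho * nxt)

    def test_da_act_lesion_gain_is_linear(self, params):
        intact = compute_da_act(1, 1.5, 4, 0.7, params, da_gain=1.0)
        lesioned = compute_da_act(1, 1.5, 4, 0.7, params, da_gain=0.5)
        assert lesioned == pytest.approx(0.5 * intact)

    def test_da_boost_hand_examples(self):
        assert compute_da_boost(1, 1.0, 10, omega=0.15) == pytest.approx(-0.5)
        assert compute_da_boost(0, 1.0, 7, omega=0.15) == 0.0
        assert compute_da_boost(1, 1.0, 1, omega=0.15) == pytest.approx(0.85)

    def test_da_boost_lesion_attenuates_reward_not_cost(self):
        # the boosting cost is charged downstream of the lesioned reward path
        assert compute_da_boost(1, 1.0, 4, omega=0.15, da_gain=0.5) == pytest.approx(
            0.5 * 1.0 - 0.15 * 4
        )

    @pytest.mark.parametrize("bad_r", [-1, 2])
    def test_invalid_reward_indicator_rejected(self, bad_r, params):
        with pytest.raises(ValueError):
            compute_da_act(bad_r, 1.0, 1, 0.0, params)
        with pytest.raises(ValueError):
            compute_da_boost(bad_r, 1.0, 1, omega=0.15)
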