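import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

import burnflow as bf
from burnflow.changepoint import (mann_whitney_components, mood_statistic,
                                  lepage_statistic, detect_change)
from burnflow.changepoint import test_flow_disturbance as flow_disturbance


def brute_force_ranks(pre, post):
    """Independent pooled-rank oracle used by the exactness tests."""
    pooled = list(pre) + list(post)
    ranks = rankdata(pooled)
    n_s, n_t = len(pre), len(post)
    n = n_s + n_t
    r_s = sum(ranks[:n_s])
    r_t = sum(ranks[n_s:])
    u_s = n_s * n_t + n_s * (n_s + 1) / 2 - r_s
    u_t = n_s * n_t + n_t * (n_t + 1) / 2 - r_t
    m_prime = sum((r - (n + 1) / 2) ** 2 for r in ranks[:n_s])
    return u_s, u_t, m_prime


class TestMannWhitney:
    def test_separated_samples(self):
        u_s, u_t, u = mann_whitney_components([1, 2, 3], [4, 5, 6])
        assert (u_s, u_t, u) == (9.0, 0.0, 0.0)

    def test_perfect_balance(self):
        u_s, u_t, u = mann_whitney_components([1, 4], [2, 3])
        assert u_s == u_t == u == 2.0

    def test_label_swap_leaves_u_unchanged(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=5)
        _, _, u1 = mann_whitney_components(a, b)
        _, _, u2 = mann_whitney_components(b, a)
        assert u1 == u2

    def test_component_sum_identity(self, rng):
        a, b = rng.integers(0, 5, 9).astype(float), rng.integers(0, 5, 7).astype(float)
        u_s, u_t, _ = mann_whitney_components(a, b)
        assert u_s + u_t == len(a) * len(b)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_components([1.0], [2.0, 3.0])


class TestMood:
    def test_pure_location_shift_has_no_scale_signal(self):
        # M' = 8.75 equals its null mean for [1,2,3] vs [4,5,6]
        assert mood_statistic([1, 2, 3], [4, 5, 6]) == pytest.approx(0.0)

    def test_spread_difference_detected(self):
        assert mood_statistic([1, 2, 5, 6], [3, 4]) > 0.0

    def test_variance_formula_hand_value(self):
        # n_S = n_T = 3: sigma^2 = 3*3*7*32/180 = 11.2
        pre, post = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        n_s = n_t = 3
        n = 6
        var = n_s * n_t * (n + 1) * (n**2 - 4) / 180
        assert var == pytest.approx(11.2)
        # and the standardized statistic uses exactly that denominator
        u_s, u_t, m_prime = brute_force_ranks(pre, post)
        assert mood_statistic(pre, post) == pytest.approx(
            abs(m_prime - n_s * (n**2 - 1) / 12) / np.sqrt(var))


class TestLepage:
    def test_balanced_location_reduces_to_mood(self):
        pre, post = [1.0, 4.0], [2.0, 3.0]
        m = mood_statistic(pre, post)
        assert lepage_statistic(pre, post) == pytest.approx(m**2)

    def test_separated_samples_value(self):
        # M = 0; U* = (0 - 4.5)/sqrt(5.25); L = 4.5^2/5.25 = 27/7
        assert lepage_statistic([1, 2, 3], [4, 5, 6]) \
            == pytest.approx(27.0 / 7.0, rel=1e-12)

    def test_null_mean_approx_two(self, rng):
        # chi^2_2 first moment under no change
        vals = [lepage_statistic(rng.normal(size=30), rng.normal(size=30))
                for _ in range(400)]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.3)

    def test_fully_tied_input_is_zero(self):
        assert lepage_statistic([2.0] * 6, [2.0] * 6) == 0.0

    @given(st.data())
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_exact_oracle_equivalence_small_n(self, data):
        n_s = data.draw(st.integers(2, 5))
        n_t = data.draw(st.integers(2, 5))
        pre = data.draw(st.lists(st.integers(0, 9), min_size=n_s, max_size=n_s))
        post = data.draw(st.lists(st.integers(0, 9), min_size=n_t, max_size=n_t))
        u_s_o, u_t_o, m_prime_o = brute_force_ranks(pre, post)
        u_s, u_t, _ = mann_whitney_components(pre, post)
        assert u_s == pytest.approx(u_s_o) and u_t == pytest.approx(u_t_o)
        n = n_s + n_t
        mu = n_s * (n**2 - 1) / 12
        var = n_s * n_t * (n + 1) * (n**2 - 4) / 180
        assert mood_statistic(pre, post) == pytest.approx(
            abs(m_prime_o - mu) / np.sqrt(var))


class TestDetectChange:
    def test_overwhelming_step_detected_and_localized(self, rng):
        x = np.concatenate([rng.normal(0, 1, 60), rng.normal(3, 1, 60)])
        res = detect_change(x, n_perm=199, seed=7)
        assert res.detected
        assert abs(res.tau - 60) <= 6

    def test_constant_series_not_detected(self):
        res = detect_change(np.full(60, 3.0), n_perm=99, seed=0)
        assert not res.detected and res.l_max == 0.0

    def test_shift_invariance(self, rng):
        x = rng.normal(size=80)
        r1 = detect_change(x, n_perm=99, seed=5)
        r2 = detect_change(x + 100.0, n_perm=99, seed=5)
        assert r1.tau == r2.tau
        assert r1.l_max == pytest.approx(r2.l_max, rel=1e-12)
        assert r1.detected == r2.detected

    def test_determinism(self, rng):
        x = rng.normal(size=80)
        r1 = detect_change(x, n_perm=99, seed=11)
        r2 = detect_change(x, n_perm=99, seed=11)
        assert r1.l_max == r2.l_max and r1.h_t == r2.h_t

    def test_profile_matches_pointwise_statistic(self, rng):
        # vectorized split profile agrees with the scalar implementation
        x = rng.normal(size=48)
        res = detect_change(x, min_segment=8, n_perm=49, seed=1)
        for i, tau in enumerate(res.taus[::5]):
            expect = lepage_statistic(x[:tau], x[tau:])
            assert res.lepage[::5][i] == pytest.approx(expect, rel=1e-10)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_change(np.arange(20.0), min_segment=12)


class TestFlowDisturbance:
    @staticmethod
    def _series(values, start="2000-01"):
        idx = pd.period_range(start, periods=len(values), freq="M")
        return pd.Series(values, index=idx)

    def test_change_well_before_fire_not_fire_linked(self, rng):
        x = np.concatenate([rng.normal(0, 1, 24), rng.normal(5, 1, 96)])
        q = self._series(x)
        res = flow_disturbance(q, "2005-01", n_perm=199, seed=3)
        assert res.detected and not res.fire_linked

    def test_change_after_fire_rejects_null(self, rng):
        x = np.concatenate([rng.normal(0, 1, 66), rng.normal(5, 1, 54)])
        q = self._series(x)  # change 6 months after the 2005-01 fire
        res = flow_disturbance(q, "2005-01", n_perm=199, seed=3)
        assert res.detected and res.fire_linked

    def test_no_change_retains_null(self, rng):
        q = self._series(rng.normal(size=120))
        res = flow_disturbance(q, "2005-01", n_perm=199, seed=3)
        assert not res.fire_linked

    def test_requires_sixty_months_each_side(self, rng):
        q = self._series(rng.normal(size=100))
        with pytest.raises(ValueError):
            flow_disturbance(q, "2005-01")
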