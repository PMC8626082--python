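"""Deviation curve, ZETA statistic, resampled nulls and Gumbel significance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from zetatest import (
    EventSeries,
    deviation_curve,
    gumbel_significance,
    isi_shuffle_null,
    jitter_null,
    pool_relative_spikes,
    zeta_statistic,
    zeta_test,
)
from zetatest.core import NullDistribution


class TestPooling:
    def test_relative_times_and_sentinels(self):
        rel = pool_relative_spikes([0.2, 0.4, 1.7], [0.0, 1.5], 1.5)
        np.testing.assert_allclose(rel.v, [0.0, 0.2, 0.2, 0.4, 1.5])
        assert rel.n == 5 and rel.q == 2

    def test_boundary_spike_at_tau_included(self):
        rel = pool_relative_spikes([2.0], [0.0, 1.0], 1.0)
        np.testing.assert_allclose(rel.v, [0.0, 1.0, 1.0])

    def test_no_spikes_gives_sentinel_only_vector(self):
        rel = pool_relative_spikes([], [0.0, 1.0], 1.0)
        np.testing.assert_allclose(rel.v, [0.0, 1.0])
        assert rel.is_empty

    def test_default_window_is_median_interval(self):
        ev = EventSeries(np.array([0.0, 1.0, 3.0, 4.0]))
        rel = pool_relative_spikes([0.5], ev)
        assert rel.tau == pytest.approx(1.0)


class TestDeviationCurve:
    def test_hand_worked_example(self):
        c = deviation_curve(np.array([0.0, 0.2, 0.4, 1.0]), tau=1.0)
        np.testing.assert_allclose(c.g, [0.25, 0.5, 0.75, 1.0])
        np.testing.assert_allclose(c.b, [0.0, 0.2, 0.4, 1.0])
        np.testing.assert_allclose(c.delta, [0.25, 0.30, 0.35, 0.0])
        np.testing.assert_allclose(c.d, [0.025, 0.075, 0.125, -0.225])

    def test_three_point_example(self):
        c = deviation_curve(np.array([0.0, 0.5, 1.0]), tau=1.0)
        np.testing.assert_allclose(c.delta, [1 / 3, 1 / 6, 0.0], atol=1e-12)
        np.testing.assert_allclose(c.d, [1 / 6, 0.0, -1 / 6], atol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40))
    def test_centered_deviations_sum_to_zero(self, vs):
        v = np.sort(np.asarray(vs))
        c = deviation_curve(v, tau=1.0)
        assert abs(c.d.sum()) < 1e-9

    def test_statistic_from_worked_example(self):
        c = deviation_curve(np.array([0.0, 0.2, 0.4, 1.0]), tau=1.0)
        zeta_raw, zeta_time, sign, inv_time = zeta_statistic(c)
        assert zeta_raw == pytest.approx(0.225)
        assert zeta_time == pytest.approx(1.0)
        assert sign == -1
        assert inv_time == pytest.approx(0.4)  # largest positive deviation

    def test_statistic_tie_breaks_to_earliest_time(self):
        curve = deviation_curve(np.array([0.0, 0.25, 0.75, 1.0]), tau=1.0)
        d = np.array([0.3, -0.3, 0.1, -0.1])
        object.__setattr__(curve, "d", d)
        _, zeta_time, sign, _ = zeta_statistic(curve)
        assert zeta_time == pytest.approx(0.0) and sign == 1


class TestTimeInvariance:
    """Circularly shifting all event times reorders the centered deviations
    without changing their values, so the statistic is shift-invariant."""

    @pytest.mark.parametrize("delta", [0.1, 0.37, 0.9])
    def test_circular_shift_reorders_d(self, rng, delta):
        tau = 1.0
        v = np.sort(rng.uniform(0, tau, size=57))
        d0 = deviation_curve(v, tau=tau).d
        v_shift = np.sort(np.mod(v - delta, tau))
        d1 = deviation_curve(v_shift, tau=tau).d
        np.testing.assert_allclose(np.sort(d0), np.sort(d1), atol=1e-12)
        z0, z1 = zeta_statistic(deviation_curve(v, tau=tau))[0], \
            zeta_statistic(deviation_curve(v_shift, tau=tau))[0]
        assert z0 == pytest.approx(z1, abs=1e-12)


class TestNullDistributions:
    def test_jitter_null_finite_positive(self, poisson_train, regular_events):
        null = jitter_null(poisson_train, regular_events, P=20, rng=0)
        assert null.P == 20
        assert np.all(np.isfinite(null.zeta_samples))
        assert np.all(null.zeta_samples > 0)

    def test_fixed_seed_bit_identical(self, poisson_train, regular_events):
        a = jitter_null(poisson_train, regular_events, P=10, rng=42)
        b = jitter_null(poisson_train, regular_events, P=10, rng=42)
        np.testing.assert_array_equal(a.zeta_samples, b.zeta_samples)
        c = isi_shuffle_null(poisson_train, regular_events, P=10, rng=42)
        d = isi_shuffle_null(poisson_train, regular_events, P=10, rng=42)
        np.testing.assert_array_equal(c.zeta_samples, d.zeta_samples)

    def test_jitter_and_isi_nulls_agree_for_poisson_train(
        self, poisson_train, regular_events
    ):
        # both are valid nulls for a homogeneous Poisson train
        a = jitter_null(poisson_train, regular_events, P=400, rng=7)
        b = isi_shuffle_null(poisson_train, regular_events, P=400, rng=8)
        assert stats.ks_2samp(a.zeta_samples, b.zeta_samples).pvalue > 0.01

    def test_null_scale_matches_order_statistic_variance(self, rng):
        # mean zeta' tracks the constant Var(d_i) = (n-1)/(12 n (n+1)) scale
        tau, q = 1.0, 50
        events = np.arange(0, q * tau, tau)
        for n in (100, 400):
            x = np.sort(rng.uniform(0, q * tau, size=n))
            null = jitter_null(x, events, tau, P=80, rng=3)
            sd_d = math.sqrt((n - 1) / (12 * (n + 1) * n))
            ratio = null.zeta_samples.mean() / sd_d
            assert 1.5 < ratio < 5.0  # max of ~n centered correlated values


class TestGumbel:
    def test_p_at_mode_is_one_minus_inv_e(self):
        samples = np.array([0.8, 1.0, 1.2, 0.9, 1.1])
        beta = math.sqrt(6 * samples.var(ddof=1)) / math.pi
        m = samples.mean() - beta * 0.5772156649015329
        p, _, fit, _ = gumbel_significance(
            NullDistribution(samples, "jitter"), m
        )
        assert p == pytest.approx(1 - math.exp(-1), rel=1e-12)
        assert fit.beta == pytest.approx(beta)

    def test_worked_example_mean1_var1(self):
        # independent evaluation: beta = sqrt(6)/pi, m = 1 - beta*gamma,
        # p = 1 - exp(-exp(-(3 - m)/beta)) ~= 0.04231
        samples = np.array([0.0, 1.0, 2.0])  # mean 1, sample var 1
        p, zc, fit, _ = gumbel_significance(
            NullDistribution(samples, "jitter"), 3.0
        )
        beta = math.sqrt(6.0) / math.pi
        m = 1.0 - beta * 0.5772156649015329
        p_expect = 1 - math.exp(-math.exp(-(3.0 - m) / beta))
        assert fit.beta == pytest.approx(beta, rel=1e-12)
        assert fit.mode_m == pytest.approx(m, rel=1e-12)
        assert p == pytest.approx(p_expect, rel=1e-9)
        assert p == pytest.approx(0.0423, abs=5e-4)
        assert zc == pytest.approx(stats.norm.isf(p / 2))

    def test_p_strictly_decreasing_in_zeta(self):
        null = NullDistribution(np.array([0.5, 1.0, 1.5, 2.0]), "jitter")
        ps = [gumbel_significance(null, z)[0] for z in np.linspace(0.1, 5, 25)]
        assert np.all(np.diff(ps) < 0)

    def test_degenerate_null_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            gumbel_significance(NullDistribution(np.ones(5), "jitter"), 1.0)

    def test_extreme_statistic_saturates_not_zero(self):
        null = NullDistribution(np.array([0.01, 0.02, 0.03]), "jitter")
        p, _, _, saturated = gumbel_significance(null, 1e6)
        assert p > 0 and saturated


class TestZetaTest:
    def test_no_spikes_flagged_p_one(self):
        res = zeta_test([], [0.0, 1.0], 1.0)
        assert res.p == 1.0 and res.zeta_raw == 0.0
        assert "no spikes" in res.flags

    def test_deterministic_given_seed(self, poisson_train, regular_events):
        a = zeta_test(poisson_train, regular_events, P=20, rng=5)
        b = zeta_test(poisson_train, regular_events, P=20, rng=5)
        assert a.p == b.p and a.zeta_raw == b.zeta_raw

    def test_isi_mode_runs(self, poisson_train, regular_events):
        res = zeta_test(poisson_train, regular_events, P=20,
                        null_mode="isi-shuffle", rng=5)
        assert 0 < res.p <= 1
        assert res.null.mode == "isi-shuffle"

    def test_strong_onset_response_detected(self, rng):
        # 100 trials with a large extra onset volley: unambiguous locking
        q, tau = 100, 1.0
        events = np.arange(q) * tau
        bg = np.sort(rng.uniform(0, q * tau, size=500))
        volley = np.repeat(events, 3) + rng.normal(0.1, 0.005, size=3 * q)
        x = np.sort(np.concatenate((bg, volley)))
        res = zeta_test(x, events, tau, rng=2)
        assert res.p < 1e-4
        assert res.zeta_corrected > 3
        assert 0.05 < res.zeta_time < 0.2
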