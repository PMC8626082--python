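"""Baseline responsiveness tests: paired t-test, PSTH ANOVAs, renewal tests."""

import numpy as np
import pytest
from scipy import special

from zetatest import (
    EpochPair,
    EventSeries,
    SurrogateSpec,
    build_psth,
    mean_rate_ttest,
    multiscale_anova,
    optimal_bin_width,
    psth_anova,
    surrogate_tests,
)
from zetatest.baselines import centered_cumulative, _ss_cost


def _train_with_counts(onsets, window, counts):
    """Spikes placed evenly inside [onset+window[0], onset+window[1])."""
    lo, hi = window
    out = []
    for onset, k in zip(onsets, counts):
        out.append(onset + lo + (np.arange(k) + 0.5) * (hi - lo) / max(k, 1))
    return np.sort(np.concatenate(out))


class TestMeanRateTTest:
    def test_matches_textbook_paired_t(self):
        onsets = np.arange(0.0, 10.0, 2.0)
        stim = [5, 6, 4, 7, 5]
        base = [1, 0, 2, 1, 1]
        x = np.sort(np.concatenate([
            _train_with_counts(onsets, (0.0, 1.0), stim),
            _train_with_counts(onsets, (1.0, 2.0), base),
        ]))
        rec = mean_rate_ttest(x, onsets, EpochPair((0, 1), (1, 2)))
        # independent textbook computation of the paired t-test
        d = np.array(stim, float) - np.array(base, float)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        p = 2.0 * special.stdtr(d.size - 1, -abs(t))
        assert rec.statistic == pytest.approx(t, rel=1e-12)
        assert rec.p == pytest.approx(p, rel=1e-12)

    def test_identical_epochs_give_p_one(self):
        onsets = np.arange(0.0, 10.0, 2.0)
        counts = [3, 3, 3, 3, 3]
        x = np.sort(np.concatenate([
            _train_with_counts(onsets, (0.0, 1.0), counts),
            _train_with_counts(onsets, (1.0, 2.0), counts),
        ]))
        rec = mean_rate_ttest(x, onsets, EpochPair((0, 1), (1, 2)))
        assert rec.p == 1.0 and rec.statistic is None

    def test_strong_rate_step_highly_significant(self, rng):
        onsets = np.arange(0.0, 200.0, 2.0)
        spikes = []
        for w in onsets:
            spikes.append(w + np.sort(rng.uniform(0, 1, rng.poisson(20))))
            spikes.append(w + 1 + np.sort(rng.uniform(0, 1, rng.poisson(5))))
        x = np.sort(np.concatenate(spikes))
        rec = mean_rate_ttest(x, onsets, EpochPair((0, 1), (1, 2)))
        assert rec.p < 1e-6

    def test_epoch_validation(self):
        with pytest.raises(ValueError, match="overlap"):
            EpochPair((0, 1), (0.5, 1.5))
        with pytest.raises(ValueError, match="positive"):
            EpochPair((0, 0), (1, 2))


class TestOptimalBinWidth:
    def test_refined_search_matches_dense_brute_force(self, rng):
        onsets = np.arange(0.0, 60.0, 2.0)
        for seed in range(3):
            local = np.random.default_rng(seed)
            # structured neuron: onset bump + background
            bump = np.repeat(onsets, 2) + local.normal(0.15, 0.03, 2 * onsets.size)
            bg = np.sort(local.uniform(0, 60, 300))
            x = np.sort(np.concatenate([bump, bg]))
            best, _ = optimal_bin_width(x, onsets, 2.0)
            dense = np.linspace(1e-3, 1.0, 500)
            dense_costs = [
                _ss_cost(build_psth(x, onsets, d, 2.0)) for d in dense
            ]
            assert _ss_cost(build_psth(x, onsets, best, 2.0)) <= min(
                dense_costs
            ) + 1e-9 * abs(min(dense_costs))

    def test_homogeneous_train_prefers_wide_bins(self, rng):
        onsets = np.arange(0.0, 200.0, 2.0)
        x = np.sort(rng.uniform(0, 200.0, 4000))
        best, curve = optimal_bin_width(x, onsets, 2.0)
        costs = dict(zip(curve[:, 0], curve[:, 1]))
        assert best > 0.25  # no structure to resolve

    def test_cost_formula_identity(self, poisson_train, regular_events):
        psth = build_psth(poisson_train, regular_events, 0.1, 2.0)
        km = psth.trial_mean
        expect = (2 * km.mean() - km.var()) / 0.1**2
        assert _ss_cost(psth) == pytest.approx(expect, rel=1e-12)


class TestPsthAnova:
    def test_matches_hand_computed_anova(self):
        # count matrix (trials x bins): [[1,5],[2,6],[1,7]]
        onsets = np.arange(0.0, 6.0, 2.0)
        b1 = _train_with_counts(onsets, (0.0, 0.5), [1, 2, 1])
        b2 = _train_with_counts(onsets, (0.5, 1.0), [5, 6, 7])
        x = np.sort(np.concatenate([b1, b2]))
        rec = psth_anova(x, onsets, 0.5, 1.0)
        g1, g2 = np.array([1, 2, 1], float), np.array([5, 6, 7], float)
        grand = np.concatenate([g1, g2]).mean()
        ssb = 3 * ((g1.mean() - grand) ** 2 + (g2.mean() - grand) ** 2)
        ssw = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
        f = (ssb / 1.0) / (ssw / 4.0)
        p = special.fdtrc(1.0, 4.0, f)
        assert rec.statistic == pytest.approx(f, rel=1e-12)
        assert rec.p == pytest.approx(p, rel=1e-12)

    def test_null_calibration(self):
        rng = np.random.default_rng(99)
        onsets = np.arange(0.0, 40.0, 2.0)
        rejected = 0
        n_sims = 1000
        for _ in range(n_sims):
            x = np.sort(rng.uniform(0, 40.0, rng.poisson(20 * 40)))
            rejected += psth_anova(x, onsets, 0.25, 1.0).p < 0.05
        assert 0.03 <= rejected / n_sims <= 0.07

    def test_onset_peak_detected(self, rng):
        onsets = np.arange(0.0, 100.0, 2.0)
        bump = np.repeat(onsets, 3) + rng.normal(0.1, 0.01, 3 * onsets.size)
        bg = np.sort(rng.uniform(0, 100, 500))
        x = np.sort(np.concatenate([bump, bg]))
        assert psth_anova(x, onsets, 0.025, 1.0).p < 1e-4

    def test_zero_variance_flagged(self):
        onsets = np.arange(0.0, 6.0, 2.0)
        x = _train_with_counts(onsets, (0.0, 0.5), [2, 2, 2])
        rec = psth_anova(x, onsets, 0.5, 1.0)
        assert rec.p == 1.0 and rec.extras["flag"] == "zero variance"


class TestMultiscaleAnova:
    def test_width_grid_and_bonferroni(self, rng):
        onsets = np.arange(0.0, 300.0, 15.0)
        x = np.sort(rng.uniform(0, 300.0, 3000))
        with pytest.warns(UserWarning, match="dropped"):
            rec = multiscale_anova(x, onsets, window=10.0)
        # widths (1/60)*2^k for k=-9..9; those allowing >=2 bins retained
        widths = (1 / 60.0) * 2.0 ** np.arange(-9, 10)
        assert rec.extras["n_widths"] == int((widths <= 5.0).sum())
        assert rec.p == pytest.approx(
            min(1.0, rec.extras["n_widths"] * rec.extras["min_uncorrected_p"])
        )

    def test_full_grid_spans_published_range(self, rng):
        onsets = np.arange(0.0, 600.0, 20.0)
        x = np.sort(rng.uniform(0, 600.0, 3000))
        rec = multiscale_anova(x, onsets, window=20.0)
        assert rec.extras["n_widths"] == 19  # 1/512th .. 512 frames all fit


class TestSurrogateTests:
    def test_centered_cumulative_hand_oracle(self):
        t0c = centered_cumulative(np.array([2.0, 0.0, 0.0, 2.0]))
        np.testing.assert_allclose(t0c, [1.0, 0.0, -1.0, 0.0])

    def test_determinism(self, poisson_train, regular_events):
        spec = SurrogateSpec("isi-shuffle", 20, "gumbel-max-cumsum", rng_seed=3)
        a = surrogate_tests(poisson_train, regular_events, 2.0, spec)
        b = surrogate_tests(poisson_train, regular_events, 2.0, spec)
        assert a.p == b.p and a.statistic == b.statistic

    @pytest.mark.parametrize("mode,stat", [
        ("poisson", "ks"),
        ("isi-shuffle", "ks"),
        ("isi-shuffle", "gumbel-max"),
        ("isi-shuffle", "gumbel-max-cumsum"),
    ])
    def test_all_variants_run_and_detect_onset_volley(self, rng, mode, stat):
        onsets = np.arange(0.0, 100.0, 2.0)
        bump = np.repeat(onsets, 4) + rng.normal(0.1, 0.005, 4 * onsets.size)
        bg = np.sort(rng.uniform(0, 100, 800))
        x = np.sort(np.concatenate([bump, bg]))
        spec = SurrogateSpec(mode, 40, stat, rng_seed=1)
        rec = surrogate_tests(x, onsets, 2.0, spec)
        assert rec.p < 0.01

    def test_null_calibration_loose(self):
        """Rejection near alpha for a homogeneous Poisson train."""
        rng = np.random.default_rng(5)
        onsets = np.arange(0.0, 50.0, 2.0)
        n_sims, alpha = 120, 0.05
        rej = {"poisson-ks": 0, "gumbel-max-cumsum": 0}
        for i in range(n_sims):
            x = np.sort(rng.uniform(0, 50.0, rng.poisson(15 * 50)))
            p1 = surrogate_tests(x, onsets, 2.0,
                                 SurrogateSpec("poisson", 2, "ks")).p
            spec = SurrogateSpec("isi-shuffle", 40, "gumbel-max-cumsum",
                                 rng_seed=i)
            p2 = surrogate_tests(x, onsets, 2.0, spec).p
            rej["poisson-ks"] += p1 < alpha
            rej["gumbel-max-cumsum"] += p2 < alpha
        for name, k in rej.items():
            assert k / n_sims <= 0.125, name  # 99% binomial band at n=120

    def test_replicate_minimum_enforced(self):
        with pytest.raises(ValueError, match="replicates"):
            SurrogateSpec("isi-shuffle", 1, "gumbel-max")
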