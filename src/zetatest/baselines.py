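"""Comparison tests for event-locked responsiveness.

These are the conventional alternatives against which the ZETA-test is
benchmarked: the paired mean-rate t-test, PSTH ANOVAs (single bin width,
Shimazaki-Shinomoto optimal width, and a Bonferroni-corrected multi-scale
set), and the renewal-process decomposition tests built from 1 ms binned
trial-averaged counts (Poisson-KS, shuffled-ISI KS, shuffled-ISI Gumbel,
and its cumulative-sum variant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import special, stats

from .core import _event_array, _seed_sequence, _spike_array, gumbel_significance
from .io import EventSeries, ResultRecord, resolve_window

__all__ = [
    "EpochPair",
    "BinnedPSTH",
    "SurrogateSpec",
    "mean_rate_ttest",
    "build_psth",
    "optimal_bin_width",
    "psth_anova",
    "multiscale_anova",
    "surrogate_tests",
]


@dataclass(frozen=True)
class EpochPair:
    """Stimulus and baseline epochs, each (start, end) seconds after onset."""

    stim_window: tuple[float, float] = (0.0, 1.0)
    base_window: tuple[float, float] = (1.0, 1.5)

    def __post_init__(self) -> None:
        for lo, hi in (self.stim_window, self.base_window):
            if hi <= lo:
                raise ValueError("epoch must have positive length")
        a, b = sorted([self.stim_window, self.base_window])
        if b[0] < a[1]:
            raise ValueError("stimulus and baseline epochs must not overlap")


def _epoch_counts(x: np.ndarray, onsets: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Per-trial spike counts in [onset+lo, onset+hi)."""
    return (
        np.searchsorted(x, onsets + hi, side="left")
        - np.searchsorted(x, onsets + lo, side="left")
    ).astype(float)


def mean_rate_ttest(spikes, events, epochs: EpochPair | None = None) -> ResultRecord:
    """Paired two-sided t-test of per-trial mean rates, stimulus vs baseline.

    Zero variance of the paired rate differences yields p = 1 with an
    undefined statistic (documented convention for screening pipelines).
    """
    if epochs is None:
        epochs = EpochPair()
    x = _spike_array(spikes)
    w = _event_array(events)
    if w.size < 2:
        raise ValueError("need at least 2 trials")
    s_lo, s_hi = epochs.stim_window
    b_lo, b_hi = epochs.base_window
    stim = _epoch_counts(x, w, s_lo, s_hi) / (s_hi - s_lo)
    base = _epoch_counts(x, w, b_lo, b_hi) / (b_hi - b_lo)
    diffs = stim - base
    nid = getattr(spikes, "neuron_id", 0)
    if np.ptp(diffs) == 0:
        return ResultRecord(nid, "mean-rate-ttest", 1.0, None,
                            {"flag": "zero-variance differences"})
    t, p = stats.ttest_rel(stim, base)
    return ResultRecord(nid, "mean-rate-ttest", float(p), float(t))


# ---------------------------------------------------------------------------
# PSTH construction and binned ANOVAs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinnedPSTH:
    """Per-trial binned spike counts over the analysis window."""

    bin_width: float
    edges: np.ndarray
    counts: np.ndarray  # (trials, bins)

    @property
    def trial_mean(self) -> np.ndarray:
        return self.counts.mean(axis=0)


def build_psth(spikes, events, bin_width: float, window=None) -> BinnedPSTH:
    """Bin event-aligned spike counts: rows are trials, columns are bins.

    Bins of uniform width tile [0, tau]; a trailing partial bin is dropped.
    """
    x = _spike_array(spikes)
    w = _event_array(events)
    win = resolve_window(
        events if isinstance(events, EventSeries) else EventSeries(w), window
    )
    n_bins = int(np.floor(win.tau / bin_width + 1e-9))
    if n_bins < 1:
        raise ValueError("bin width exceeds the analysis window")
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.empty((w.size, n_bins))
    for i, onset in enumerate(w):
        counts[i] = np.diff(np.searchsorted(x, onset + edges, side="left"))
    return BinnedPSTH(bin_width, edges, counts)


def _ss_cost(psth: BinnedPSTH) -> float:
    """Shimazaki-Shinomoto cost C = (2*kbar - v) / delta^2 from the mean and
    (biased) variance of the trial-mean per-bin counts."""
    km = psth.trial_mean
    kbar = km.mean()
    v = km.var()  # ddof=0, as in the original rule
    return float((2.0 * kbar - v) / psth.bin_width**2)


def optimal_bin_width(
    spikes,
    events,
    window=None,
    bounds: tuple[float, float] | None = None,
    rel_tol: float = 1e-3,
) -> tuple[float, np.ndarray]:
    """Shimazaki-Shinomoto optimal PSTH bin width by iterative grid search.

    A 10-point grid over ``bounds`` (default [1 ms, tau/2]) is repeatedly
    refined around the current cost minimizer until the bracket's relative
    span falls below ``rel_tol``. Returns (best width, evaluated (width,
    cost) pairs sorted by width).
    """
    x = _spike_array(spikes)
    if x.size < 1:
        raise ValueError("need at least 1 spike")
    w = _event_array(events)
    win = resolve_window(
        events if isinstance(events, EventSeries) else EventSeries(w), window
    )
    if bounds is None:
        bounds = (1e-3, win.tau / 2.0)
    lo, hi = bounds
    seen: dict[float, float] = {}

    def cost(delta: float) -> float:
        if delta not in seen:
            seen[delta] = _ss_cost(build_psth(x, w, delta, win))
        return seen[delta]

    while True:
        grid = np.linspace(lo, hi, 10)
        costs = np.array([cost(d) for d in grid])
        i = int(np.argmin(costs))
        best = grid[i]
        new_lo = grid[max(i - 1, 0)]
        new_hi = grid[min(i + 1, 9)]
        if (new_hi - new_lo) / best < rel_tol:
            break
        lo, hi = new_lo, new_hi
    curve = np.array(sorted(seen.items()))
    if not np.isfinite(curve[:, 1]).any():
        raise ValueError("degenerate cost curve (all-empty bins)")
    return float(best), curve


def psth_anova(spikes, events, bin_width: float, window=None) -> ResultRecord:
    """One-way ANOVA across PSTH bins, with per-trial counts as replicates."""
    psth = build_psth(spikes, events, bin_width, window)
    if psth.counts.shape[1] < 2:
        raise ValueError("need at least 2 bins for an ANOVA")
    nid = getattr(spikes, "neuron_id", 0)
    groups = [psth.counts[:, j] for j in range(psth.counts.shape[1])]
    if all(np.ptp(g) == 0 for g in groups):
        return ResultRecord(nid, "psth-anova", 1.0, None,
                            {"bin_width": bin_width, "flag": "zero variance"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    if not np.isfinite(p):
        return ResultRecord(nid, "psth-anova", 1.0, None,
                            {"bin_width": bin_width, "flag": "undefined F"})
    return ResultRecord(nid, "psth-anova", float(p), float(f),
                        {"bin_width": bin_width})


def multiscale_anova(
    spikes, events, window=None, center_bin: float = 1.0 / 60.0, steps: int = 9
) -> ResultRecord:
    """Bonferroni-corrected set of PSTH ANOVAs on a base-2 grid of widths.

    Widths are center_bin * 2**k for k = -steps..+steps (19 by default);
    widths exceeding the window are dropped with a warning. The reported p
    is min(1, n_widths * min_k p_k) and the winning width is recorded.
    """
    w = _event_array(events)
    win = resolve_window(
        events if isinstance(events, EventSeries) else EventSeries(w), window
    )
    widths = center_bin * 2.0 ** np.arange(-steps, steps + 1)
    usable = widths[widths <= win.tau / 2.0]  # need at least 2 bins
    if usable.size < widths.size:
        warnings.warn(
            f"dropped {widths.size - usable.size} bin widths exceeding the window",
            stacklevel=2,
        )
    if usable.size == 0:
        raise ValueError("no usable bin widths within the window")
    records = [psth_anova(spikes, events, bw, win) for bw in usable]
    ps = np.array([r.p for r in records])
    i = int(np.argmin(ps))
    p_corr = min(1.0, usable.size * float(ps[i]))
    nid = getattr(spikes, "neuron_id", 0)
    return ResultRecord(
        nid, "multiscale-anova", p_corr, records[i].statistic,
        {"best_bin_width": float(usable[i]), "n_widths": int(usable.size),
         "min_uncorrected_p": float(ps[i])},
    )


# ---------------------------------------------------------------------------
# Renewal-process decomposition tests (1 ms binned)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateSpec:
    """Configuration for the decomposition tests.

    mode 'poisson' + statistic 'ks'            -> Poiss-KS
    mode 'isi-shuffle' + statistic 'ks'        -> SISI-KS
    mode 'isi-shuffle' + 'gumbel-max'          -> SISI-G
    mode 'isi-shuffle' + 'gumbel-max-cumsum'   -> SISI-integral-G
    """

    mode: Literal["poisson", "isi-shuffle"] = "isi-shuffle"
    replicates: int = 100
    statistic: Literal["ks", "gumbel-max", "gumbel-max-cumsum"] = "gumbel-max-cumsum"
    rng_seed: int | None = None
    two_sample_poisson: bool = False  # sample the Poisson null instead of its CDF

    def __post_init__(self) -> None:
        if self.statistic.startswith("gumbel") and self.replicates < 2:
            raise ValueError("gumbel statistics need at least 2 replicates")


def centered_cumulative(x: np.ndarray) -> np.ndarray:
    """Mean-centered cumulative count deviation: cumsum(x - mean(x)),
    itself mean-centered to remove the zero-variance fixed endpoints."""
    t0 = np.cumsum(x - x.mean())
    return t0 - t0.mean()


def _max_deviation(x: np.ndarray, statistic: str) -> float:
    if statistic == "gumbel-max":
        return float(np.abs(x - x.mean()).max())
    return float(np.abs(centered_cumulative(x)).max())


def surrogate_tests(
    spikes, events, window=None, spec: SurrogateSpec | None = None,
    bin_width: float = 1e-3,
) -> ResultRecord:
    """Renewal-process tests on 1 ms binned trial-averaged spike counts.

    The observed trial-averaged count vector is compared with a null model
    that is either analytic (trial-averaged homogeneous Poisson) or built
    from inter-spike-interval-shuffled surrogate trains, using either a
    Kolmogorov-Smirnov distance or a Gumbel p-value of the most extreme
    (optionally cumulative) deviation.
    """
    if spec is None:
        spec = SurrogateSpec()
    x = _spike_array(spikes)
    w = _event_array(events)
    win = resolve_window(
        events if isinstance(events, EventSeries) else EventSeries(w), window
    )
    psth = build_psth(x, w, bin_width, win)
    T = psth.counts.shape[0]
    avg = psth.trial_mean
    nid = getattr(spikes, "neuron_id", 0)
    name = f"{spec.mode}-{spec.statistic}"

    if spec.mode == "poisson":
        lam = avg.mean()  # per-trial per-bin Poisson mean
        if spec.two_sample_poisson:
            rng = np.random.default_rng(_seed_sequence(spec.rng_seed))
            sample = rng.poisson(T * lam, size=(spec.replicates, avg.size)) / T
            stat, p = stats.ks_2samp(avg, sample.ravel())
        else:
            # average of T Poisson counts: T*avg ~ Pois(T*lam). The null is
            # discrete, so the KS distance is taken over the atoms k/T
            # (right limits of both step functions); the asymptotic
            # continuous p-value is conservative here.
            kcounts = np.rint(avg * T).astype(int)
            kmax = int(stats.poisson.isf(1e-12, T * lam)) + kcounts.max() + 1
            atoms = np.arange(kmax + 1)
            null_cdf = stats.poisson.cdf(atoms, T * lam)
            ecdf = np.searchsorted(np.sort(kcounts), atoms, side="right") / avg.size
            stat = float(np.abs(ecdf - null_cdf).max())
            p = float(special.kolmogorov(stat * np.sqrt(avg.size)))
        return ResultRecord(nid, name, float(min(p, 1.0)), float(stat),
                            {"bin_width": bin_width})

    # ISI-shuffled surrogate trains, evaluated against the original events
    if x.size < 3:
        raise ValueError("ISI shuffling needs at least 3 spikes")
    if spec.replicates < 2:
        raise ValueError("need at least 2 surrogate replicates")
    dt = np.diff(x)
    edges = psth.edges
    surr = np.empty((spec.replicates, avg.size))
    for j, child in enumerate(_seed_sequence(spec.rng_seed).spawn(spec.replicates)):
        sub = np.random.default_rng(child)
        t0 = x[0] + np.concatenate(([0.0], np.cumsum(sub.permutation(dt))))
        counts = np.empty((T, avg.size))
        for i, onset in enumerate(w):
            counts[i] = np.diff(np.searchsorted(t0, onset + edges, side="left"))
        surr[j] = counts.mean(axis=0)

    if spec.statistic == "ks":
        stat, p = stats.ks_2samp(avg, surr.ravel())
        return ResultRecord(nid, name, float(p), float(stat),
                            {"bin_width": bin_width})

    obs = _max_deviation(avg, spec.statistic)
    null_stats = np.array([_max_deviation(s, spec.statistic) for s in surr])
    try:
        p, _, _, saturated = gumbel_significance(null_stats, obs)
    except ValueError:
        return ResultRecord(nid, name, 1.0, obs,
                            {"bin_width": bin_width, "flag": "degenerate null"})
    extras = {"bin_width": bin_width}
    if saturated:
        extras["flag"] = "saturated"
    return ResultRecord(nid, name, p, obs, extras)
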