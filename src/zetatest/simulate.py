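"""Ground-truth spike-train simulators for benchmarking responsiveness tests.

Four generators cover the benchmark conditions: orientation-tuned Poisson
neurons (mean-rate modulation only), a rate-difference / response-duration
grid (tri-phasic responses with conserved spike counts), orientation-tuned
bursting neurons (temporal structure with matched rate distributions), and
constant-rate neurons carrying a single jittered extra spike per trial for
peak-latency benchmarking. ``make_null_twin`` produces event-unlocked
copies used as the negative class in ROC analyses.

Homogeneous-rate segments are realized by drawing a Poisson spike count for
the segment and placing the spikes uniformly, which is the same point
process as consecutive exponential inter-spike intervals but vectorizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Literal

import numpy as np
from scipy.special import i0

from .core import _seed_sequence
from .io import EventSeries, SpikeTrain

__all__ = [
    "TunedPoissonParams",
    "RateDurationGridParams",
    "BurstingParams",
    "PeakSimParams",
    "SimPopulation",
    "simulate_tuned_poisson",
    "draw_tuned_poisson_rates",
    "simulate_rate_duration_grid",
    "simulate_bursting",
    "simulate_peak_latency",
    "make_null_twin",
]


@dataclass(frozen=True)
class SimPopulation:
    """A simulated population: one spike train and event series per neuron,
    with ground-truth modulation labels for ROC benchmarking."""

    trains: list[SpikeTrain]
    events: list[EventSeries]
    modulated: np.ndarray  # bool per neuron
    truth: list[dict[str, Any]]
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    def firing_rates(self) -> np.ndarray:
        """Overall firing rate per neuron (total spikes / total duration)."""
        dur = self.meta["duration"]
        return np.array([t.n_spikes / dur for t in self.trains])


def _segment_poisson(
    rng: np.random.Generator, starts: np.ndarray, durs: np.ndarray, rates: np.ndarray
) -> np.ndarray:
    """Spikes of a piecewise-homogeneous Poisson process (sorted)."""
    counts = rng.poisson(rates * durs)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    u = rng.uniform(size=total)
    t = np.repeat(starts, counts) + u * np.repeat(durs, counts)
    t.sort(kind="stable")
    return t


def _von_mises_pdf(x: np.ndarray, theta: float, kappa: float) -> np.ndarray:
    return np.exp(kappa * np.cos(x - theta)) / (2.0 * np.pi * i0(kappa))


# ---------------------------------------------------------------------------
# Orientation-tuned Poisson neurons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TunedPoissonParams:
    """Mean-rate modulated Poisson neurons with two-lobed von Mises tuning."""

    n_neurons: int = 100
    lambda_base: float = 5.0     # Hz, mean of the exponential baseline rate
    rate_gain: float = 20.0      # Hz, mean preferred-rate excess over baseline
    kappa_base: float = 5.0
    kappa_jitter: float = 5.0    # kappa ~ kappa_base + U(0, kappa_jitter)
    directions_deg: tuple[float, ...] = tuple(range(0, 360, 45))
    repeats: int = 20
    stim_dur: float = 1.0        # s
    iti_dur: float = 1.0         # s


def draw_tuned_poisson_rates(
    n: int, rng, lambda_base: float = 5.0, rate_gain: float = 20.0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (mu_base, mu_stim) rate parameters for n neurons.

    mu_base ~ Exp(mean lambda_base); mu_stim ~ Exp(mean mu_base + gain), so
    the population means are lambda_base and lambda_base + gain.
    """
    gen = np.random.default_rng(_seed_sequence(rng))
    mu_base = gen.exponential(lambda_base, size=n)
    mu_stim = gen.exponential(mu_base + rate_gain)
    return mu_base, mu_stim


def simulate_tuned_poisson(
    params: TunedPoissonParams | None = None, rng=None
) -> SimPopulation:
    """Simulate orientation-tuned Poisson neurons.

    Each neuron's direction tuning is the sum of two von Mises lobes at its
    preferred orientation theta and theta + pi, rescaled to run from
    mu_base (trough, and inter-trial rate) to mu_stim (preferred rate).
    """
    p = params or TunedPoissonParams()
    master = np.random.default_rng(_seed_sequence(rng))
    dirs_rad = np.deg2rad(np.array(p.directions_deg, dtype=float))
    n_trials = p.repeats * dirs_rad.size
    trial_len = p.stim_dur + p.iti_dur
    dir_seq = master.permutation(np.tile(np.arange(dirs_rad.size), p.repeats))
    onsets = np.arange(n_trials) * trial_len
    labels = tuple(f"{p.directions_deg[i]:g}" for i in dir_seq)
    events = EventSeries(onsets, labels)

    mu_base, mu_stim = draw_tuned_poisson_rates(
        p.n_neurons, master, p.lambda_base, p.rate_gain
    )
    trains, truth = [], []
    for idx in range(p.n_neurons):
        theta = master.uniform(0.0, np.pi)
        kappa = p.kappa_base + master.uniform(0.0, p.kappa_jitter)
        lobes = _von_mises_pdf(dirs_rad, theta, kappa) + _von_mises_pdf(
            dirs_rad, theta + np.pi, kappa
        )
        grid = np.linspace(0, 2 * np.pi, 721)
        f = _von_mises_pdf(grid, theta, kappa) + _von_mises_pdf(grid, theta + np.pi, kappa)
        f_min, f_max = f.min(), f.max()
        shape = (lobes - f_min) / (f_max - f_min)
        stim_rates = mu_base[idx] + (mu_stim[idx] - mu_base[idx]) * shape[dir_seq]
        starts = np.empty(2 * n_trials)
        durs = np.empty(2 * n_trials)
        rates = np.empty(2 * n_trials)
        starts[0::2], starts[1::2] = onsets, onsets + p.stim_dur
        durs[0::2], durs[1::2] = p.stim_dur, p.iti_dur
        rates[0::2], rates[1::2] = stim_rates, mu_base[idx]
        t = _segment_poisson(master, starts, durs, rates)
        trains.append(SpikeTrain(t, idx))
        truth.append(
            {"theta": theta, "kappa": kappa,
             "mu_base": mu_base[idx], "mu_stim": mu_stim[idx]}
        )
    return SimPopulation(
        trains,
        [events] * p.n_neurons,
        np.ones(p.n_neurons, dtype=bool),
        truth,
        {"generator": "tuned-poisson", "duration": n_trials * trial_len,
         "params": p},
    )


# ---------------------------------------------------------------------------
# Rate-difference / response-duration grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateDurationGridParams:
    """One grid point of the rate-difference (dHz) x response-duration (T_r)
    benchmark: tri-phasic responses with conserved stimulus spike count."""

    dHz: float = 0.0             # 0..1 Hz rate excess over background
    T_r: float = 1.0             # (0, 1] s active period within the stimulus
    background: float = 1.0      # Hz
    stim_dur: float = 1.0
    iti_dur: float = 1.0
    trials: int = 100
    n_neurons: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.T_r <= self.stim_dur):
            raise ValueError("T_r must lie in (0, stim_dur]")
        if self.dHz < 0:
            raise ValueError("dHz must be non-negative")


def simulate_rate_duration_grid(
    params: RateDurationGridParams, rng=None
) -> SimPopulation:
    """Simulate tri-phasic Poisson neurons for one (dHz, T_r) grid point.

    During the stimulus second the rate is (background + dHz)/T_r for the
    first T_r seconds and 0 afterwards, so the expected stimulus-second
    spike count is background + dHz regardless of T_r; the inter-trial
    second runs at the background rate.
    """
    p = params
    master = np.random.default_rng(_seed_sequence(rng))
    trial_len = p.stim_dur + p.iti_dur
    onsets = np.arange(p.trials) * trial_len
    events = EventSeries(onsets)
    active_rate = (p.background * p.stim_dur + p.dHz) / p.T_r
    starts = np.empty(2 * p.trials)
    durs = np.empty(2 * p.trials)
    rates = np.empty(2 * p.trials)
    starts[0::2], starts[1::2] = onsets, onsets + p.stim_dur
    durs[0::2], durs[1::2] = p.T_r, p.iti_dur
    rates[0::2], rates[1::2] = active_rate, p.background
    trains = [
        SpikeTrain(_segment_poisson(master, starts, durs, rates), i)
        for i in range(p.n_neurons)
    ]
    modulated = (p.dHz > 0) or (p.T_r < p.stim_dur)
    return SimPopulation(
        trains,
        [events] * p.n_neurons,
        np.full(p.n_neurons, modulated),
        [{"dHz": p.dHz, "T_r": p.T_r}] * p.n_neurons,
        {"generator": "rate-duration-grid", "duration": p.trials * trial_len,
         "params": p},
    )


# ---------------------------------------------------------------------------
# Bursting neurons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BurstingParams:
    """Orientation-tuned bursting neurons.

    Each neuron superimposes a sparse single-spike Poisson process (rate
    r ~ Exp(mean 1) Hz) and a burst process whose onset intensity is R_b
    (baseline/non-preferred, R_b ~ |N|/20 + 1/80, mean inter-burst interval
    ~16 s) plus a von Mises lobe R_t * VM(theta_p, kappa) during stimuli
    (R_t ~ |N| + 1/4; at the preferred direction the mean inter-burst
    interval drops to ~0.8 s). Each burst expands into spikes over a
    Gamma(2k_dur, 0.5) ms duration with Gamma(2k_isi, 0.5) ms intra-burst
    intervals. Unresponsive neurons use one fixed inter-burst interval
    (~6.8 s) throughout, chosen so that the two populations' firing-rate
    distributions overlap.
    """

    n_neurons: int = 1000
    responsive: bool = True
    n_directions: int = 24       # 15 degree steps
    repeats: int = 20
    stim_dur: float = 1.0        # s (grating protocol: 1 s stim, 0.5 s ITI)
    iti_dur: float = 0.5
    unresponsive_ibi: float = 6.8  # s
    single_spike_rate_mean: float = 1.0  # Hz
    dur_k_mean: float = 90.0     # burst duration ~ Gamma(2k, 0.5) ms, k ~ N(mean, sd)
    dur_k_sd: float = 10.0
    isi_k_base: float = 0.5      # intra-burst ISI ~ Gamma(2k, 0.5) ms,
    isi_k_exp_rate: float = 1.0 / 1.1  # k ~ base + Exp(1/rate); scale fixed
    # by the population firing-rate calibration (see docs/methods.md)


def _positive(draw, *args) -> float:
    """Redraw until strictly positive (avoids atoms at zero)."""
    while True:
        val = float(draw(*args))
        if val > 0:
            return val


def _expand_bursts(
    rng: np.random.Generator,
    burst_onsets: np.ndarray,
    k_dur: float,
    k_isi: float,
) -> np.ndarray:
    """Expand burst onset times into intra-burst spike trains."""
    n_b = burst_onsets.size
    if n_b == 0:
        return np.empty(0)
    durs = rng.gamma(2.0 * k_dur, 0.5, size=n_b) * 1e-3  # s
    mean_isi = k_isi * 1e-3
    spikes = [burst_onsets]
    remaining = np.arange(n_b)
    offset = np.zeros(n_b)
    while remaining.size:
        m = int(np.ceil(durs[remaining].max() / mean_isi * 1.3 + 10))
        isis = rng.gamma(2.0 * k_isi, 0.5, size=(remaining.size, m)) * 1e-3
        cum = offset[remaining, None] + np.cumsum(isis, axis=1)
        keep = cum <= durs[remaining, None]
        spikes.append((burst_onsets[remaining, None] + cum)[keep])
        unfinished = keep.all(axis=1)  # burst not yet exhausted: top up
        offset[remaining[unfinished]] = cum[unfinished, -1]
        remaining = remaining[unfinished]
    out = np.concatenate(spikes)
    out.sort(kind="stable")
    return out


def simulate_bursting(
    params: BurstingParams | None = None, rng=None
) -> SimPopulation:
    """Simulate a population of independently parameterized bursting neurons."""
    p = params or BurstingParams()
    master = np.random.default_rng(_seed_sequence(rng))
    trial_len = p.stim_dur + p.iti_dur
    n_trials = p.repeats * p.n_directions
    total_dur = n_trials * trial_len
    dirs_rad = np.arange(p.n_directions) * (2.0 * np.pi / p.n_directions)
    dir_seq = master.permutation(np.tile(np.arange(p.n_directions), p.repeats))
    onsets = np.arange(n_trials) * trial_len
    labels = tuple(f"{np.rad2deg(dirs_rad[i]):g}" for i in dir_seq)
    events = EventSeries(onsets, labels)

    trains, truth = [], []
    for idx in range(p.n_neurons):
        r_single = _positive(master.exponential, p.single_spike_rate_mean)
        R_b = abs(master.standard_normal()) / 20.0 + 1.0 / 80.0
        R_t = abs(master.standard_normal()) + 0.25
        theta_p = master.uniform(0.0, 2.0 * np.pi)
        kappa = 5.0 + master.uniform(0.0, 5.0)
        k_dur = _positive(lambda: p.dur_k_mean + p.dur_k_sd * master.standard_normal())
        k_isi = p.isi_k_base + master.exponential(1.0 / p.isi_k_exp_rate)

        single = _segment_poisson(
            master, np.array([0.0]), np.array([total_dur]), np.array([r_single])
        )
        if p.responsive:
            stim_intensity = R_b + R_t * _von_mises_pdf(dirs_rad[dir_seq], theta_p, kappa)
            starts = np.empty(2 * n_trials)
            durs = np.empty(2 * n_trials)
            rates = np.empty(2 * n_trials)
            starts[0::2], starts[1::2] = onsets, onsets + p.stim_dur
            durs[0::2], durs[1::2] = p.stim_dur, p.iti_dur
            rates[0::2], rates[1::2] = stim_intensity, R_b
            burst_onsets = _segment_poisson(master, starts, durs, rates)
        else:
            burst_onsets = _segment_poisson(
                master,
                np.array([0.0]),
                np.array([total_dur]),
                np.array([1.0 / p.unresponsive_ibi]),
            )
        burst_spikes = _expand_bursts(master, burst_onsets, k_dur, k_isi)
        t = np.concatenate((single, burst_spikes))
        t = t[t <= total_dur]
        t.sort(kind="stable")
        trains.append(SpikeTrain(t, idx))
        truth.append(
            {"r_single": r_single, "R_b": R_b, "R_t": R_t, "theta_p": theta_p,
             "kappa": kappa, "k_dur": k_dur, "k_isi": k_isi}
        )
    return SimPopulation(
        trains,
        [events] * p.n_neurons,
        np.full(p.n_neurons, p.responsive),
        truth,
        {"generator": "bursting", "duration": total_dur, "params": p},
    )


# ---------------------------------------------------------------------------
# Peak-latency benchmark neurons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakSimParams:
    """Constant-rate Poisson neurons with one extra, jittered spike in half
    of all trials, for peak-latency recovery benchmarks."""

    base_rate: float = 10.0      # Hz
    jitter_sigma: float = 2e-3   # s, SD of the added-spike time
    trials: int = 100
    trial_dur: float = 2.0       # s
    peak_center_range: tuple[float, float] = (0.090, 0.110)  # s after onset
    peak_prob: float = 0.5
    n_neurons: int = 1


def simulate_peak_latency(
    params: PeakSimParams | None = None, rng=None
) -> SimPopulation:
    """Simulate peak-latency benchmark neurons; ground-truth peak recorded."""
    p = params or PeakSimParams()
    master = np.random.default_rng(_seed_sequence(rng))
    onsets = np.arange(p.trials) * p.trial_dur
    events = EventSeries(onsets)
    trains, truth = [], []
    for idx in range(p.n_neurons):
        center = master.uniform(*p.peak_center_range)
        bg = _segment_poisson(
            master,
            np.array([0.0]),
            np.array([p.trials * p.trial_dur]),
            np.array([p.base_rate]),
        )
        n_peak = int(round(p.peak_prob * p.trials))
        which = master.choice(p.trials, size=n_peak, replace=False)
        peaks = onsets[which] + master.normal(center, p.jitter_sigma, size=n_peak)
        t = np.concatenate((bg, peaks))
        t = t[(t >= 0)]
        t.sort(kind="stable")
        trains.append(SpikeTrain(t, idx))
        truth.append({"peak_center": center, "sigma": p.jitter_sigma,
                      "base_rate": p.base_rate})
    return SimPopulation(
        trains,
        [events] * p.n_neurons,
        np.ones(p.n_neurons, dtype=bool),
        truth,
        {"generator": "peak-latency", "duration": p.trials * p.trial_dur,
         "params": p},
    )


# ---------------------------------------------------------------------------
# Event-unlocked twins
# ---------------------------------------------------------------------------

def make_null_twin(
    population: SimPopulation,
    mode: Literal["jitter", "isi-shuffle"] = "jitter",
    jitter: float | None = None,
    rng=None,
) -> SimPopulation:
    """Destroy event-locking while preserving spike-train structure.

    jitter mode displaces each neuron's event onsets independently by
    U(-J, +J) (J defaults to the median onset-to-onset interval) and leaves
    the spikes untouched; isi-shuffle mode permutes each train's
    inter-spike intervals and leaves the events untouched.
    """
    master = np.random.default_rng(_seed_sequence(rng))
    trains, events = [], []
    for train, evs in zip(population.trains, population.events):
        if mode == "jitter":
            J = jitter if jitter is not None else evs.median_interval()
            w = np.sort(evs.onsets + master.uniform(-J, J, size=evs.q))
            events.append(EventSeries(w))
            trains.append(train)
        elif mode == "isi-shuffle":
            x = train.times
            if x.size >= 3:
                dt = master.permutation(np.diff(x))
                x = x[0] + np.concatenate(([0.0], np.cumsum(dt)))
            trains.append(SpikeTrain(x, train.neuron_id))
            events.append(evs)
        else:
            raise ValueError(f"unknown twin mode {mode!r}")
    return SimPopulation(
        trains,
        events,
        np.zeros(population.n_neurons, dtype=bool),
        [dict(t, twin=mode) for t in population.truth],
        {**population.meta, "twin": mode},
    )
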