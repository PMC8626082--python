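"""The ZETA statistic: deviation curve, resampled nulls, Gumbel significance.

The ZETA-test asks whether a neuron's spiking is time-locked to a series of
events, without binning and without free parameters. Spikes are pooled
relative to the most recent event onset into a vector ``v`` on [0, tau];
the neuron's empirical cumulative spike fraction ``g`` is compared with the
linear baseline ``b = v/tau`` expected for an unmodulated rate. The maximum
absolute value of the mean-centered difference ``d`` is the raw statistic
zeta_r. Its significance comes from resampling (event-onset jitter, or
inter-spike-interval shuffling) and a Gumbel fit to the resampled maxima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .io import AnalysisWindow, EventSeries, SpikeTrain, resolve_window

__all__ = [
    "RelativeSpikeVector",
    "DeviationCurve",
    "NullDistribution",
    "GumbelFit",
    "ZetaResult",
    "pool_relative_spikes",
    "deviation_curve",
    "zeta_statistic",
    "jitter_null",
    "isi_shuffle_null",
    "gumbel_significance",
    "zeta_test",
]

EULER_GAMMA = 0.5772156649015329  # Euler-Mascheroni constant

NullMode = Literal["jitter", "isi-shuffle"]


# ---------------------------------------------------------------------------
# Input coercion
# ---------------------------------------------------------------------------

def _spike_array(spikes) -> np.ndarray:
    if isinstance(spikes, SpikeTrain):
        return spikes.times
    arr = np.sort(np.asarray(spikes, dtype=float), kind="stable")
    return arr


def _event_array(events) -> np.ndarray:
    if isinstance(events, EventSeries):
        return events.onsets
    return np.asarray(events, dtype=float)


def _seed_sequence(rng) -> np.random.SeedSequence:
    """Normalize ``rng`` (None | int | SeedSequence | Generator) to a
    SeedSequence so per-resample substreams derive deterministically."""
    if rng is None:
        return np.random.SeedSequence()
    if isinstance(rng, np.random.SeedSequence):
        return rng
    if isinstance(rng, (int, np.integer)):
        return np.random.SeedSequence(int(rng))
    if isinstance(rng, np.random.Generator):
        return np.random.SeedSequence(int(rng.integers(2**31)))
    raise TypeError(f"cannot interpret {rng!r} as a random seed")


# ---------------------------------------------------------------------------
# Deviation curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelativeSpikeVector:
    """Pooled relative spike times on [0, tau], with sentinels at 0 and tau.

    ``n`` counts the two sentinel entries; ``n_real = n - 2`` is the number
    of observed spikes that fell inside an event window.
    """

    v: np.ndarray
    tau: float
    q: int

    @property
    def n(self) -> int:
        return self.v.size

    @property
    def n_real(self) -> int:
        return self.n - 2

    @property
    def is_empty(self) -> bool:
        return self.n_real <= 0


def _pool(x: np.ndarray, w: np.ndarray, tau: float) -> np.ndarray:
    """Relative spike times in (0, tau] pooled over per-event windows,
    plus sentinels at 0 and tau; sorted.

    Each event window (w_k, w_k + tau] contributes its spikes relative to
    w_k. When windows do not overlap (the usual design, tau at most the
    onset spacing) this equals referring each spike to its most recent
    onset; when resampled onsets make windows overlap, a spike enters every
    window that contains it, which keeps the pooled relative-time density
    uniform for a stationary train and hence the resampled null calibrated.
    """
    if x.size and w.size:
        lo = np.searchsorted(x, w, side="right")         # first spike > w_k
        hi = np.searchsorted(x, w + tau, side="right")   # last spike <= w_k + tau
        counts = hi - lo
        total = int(counts.sum())
        cs = np.concatenate(([0], np.cumsum(counts[:-1])))
        idx = np.repeat(lo, counts) + np.arange(total) - np.repeat(cs, counts)
        v = x[idx] - np.repeat(w, counts)
    else:
        v = np.empty(0)
    v = np.concatenate((v, [0.0, tau]))
    v.sort(kind="stable")
    return v


def pool_relative_spikes(spikes, events, window=None) -> RelativeSpikeVector:
    """Pool spike times relative to the most recent event onset.

    Each spike ``x_i`` is referred to the onset ``w_k`` with
    ``w_k < x_i <= w_{k+1}``; only relative times in (0, tau] are kept.
    Two sentinel entries at 0 and tau guarantee coverage of the window.
    """
    x = _spike_array(spikes)
    w = _event_array(events)
    if w.size < 2:
        raise ValueError("need at least 2 events")
    win = resolve_window(
        events if isinstance(events, EventSeries) else EventSeries(w), window
    )
    return RelativeSpikeVector(_pool(x, w, win.tau), win.tau, int(w.size))


@dataclass(frozen=True)
class DeviationCurve:
    """Cumulative-fraction deviation of a spike train from a uniform rate.

    g_i = i/n is the empirical cumulative spike fraction at spike i,
    b_i = v_i/tau the linear baseline, delta = g - b their difference and
    d = delta - mean(delta) its mean-centered (time-invariant) version.
    """

    v: np.ndarray
    tau: float
    q: int
    g: np.ndarray
    b: np.ndarray
    delta: np.ndarray
    d: np.ndarray


def deviation_curve(rel, tau: float | None = None, q: int = 1) -> DeviationCurve:
    """Build the deviation curve from a RelativeSpikeVector (or a raw sorted
    array of relative times, in which case ``tau`` must be given)."""
    if isinstance(rel, RelativeSpikeVector):
        v, tau, q = rel.v, rel.tau, rel.q
    else:
        v = np.asarray(rel, dtype=float)
        if tau is None:
            raise ValueError("tau is required when passing a raw time array")
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 relative spike times")
    g = np.arange(1, n + 1) / n
    b = v / tau
    delta = g - b
    d = delta - delta.mean()
    return DeviationCurve(v, float(tau), q, g, b, delta, d)


def zeta_statistic(curve: DeviationCurve) -> tuple[float, float, int, float]:
    """Return (zeta_raw, zeta_time, zeta_sign, inverse_zeta_time).

    zeta_raw = max|d|; zeta_time is the relative time at which it occurs
    (ties broken by earliest time); inverse_zeta_time is the time of the
    most extreme deviation of opposite sign.
    """
    d = curve.d
    i_max = int(np.argmax(np.abs(d)))  # first occurrence = earliest time
    zeta_raw = float(abs(d[i_max]))
    zeta_time = float(curve.v[i_max])
    sign = int(np.sign(d[i_max]))
    if sign > 0:
        i_inv = int(np.argmin(d))
    elif sign < 0:
        i_inv = int(np.argmax(d))
    else:
        i_inv = i_max
    return zeta_raw, zeta_time, sign, float(curve.v[i_inv])


# ---------------------------------------------------------------------------
# Null distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NullDistribution:
    """Resampled null samples zeta'(j) of the ZETA statistic."""

    zeta_samples: np.ndarray
    mode: str
    n_flagged: int = 0  # resamples that had no spikes in any window

    @property
    def P(self) -> int:
        return self.zeta_samples.size


def _null_zeta_one(
    vprime: np.ndarray, v: np.ndarray, b: np.ndarray
) -> tuple[float, bool]:
    """One null sample: interpolate the resampled cumulative fraction onto
    the original spike times and take the max absolute centered deviation."""
    nprime = vprime.size
    if nprime <= 2:  # sentinels only: no spikes landed in any window
        return 0.0, True
    f = np.arange(1, nprime + 1) / nprime
    g_prime = np.interp(v, vprime, f)
    d_prime = g_prime - b
    d_prime -= d_prime.mean()
    return float(np.abs(d_prime).max()), False


def jitter_null(
    spikes, events, window=None, P: int = 100, rng=None
) -> NullDistribution:
    """Null distribution from event-onset jittering.

    Each resample displaces every event time independently by a uniform
    offset on [-tau, +tau], re-pools the spikes, and evaluates the maximum
    absolute centered deviation at the original spike times.
    """
    if P < 2:
        raise ValueError("need at least 2 resamples")
    x = _spike_array(spikes)
    w = _event_array(events)
    rel = pool_relative_spikes(x, w, window)
    curve = deviation_curve(rel)
    tau = rel.tau
    samples = np.empty(P)
    flagged = 0
    for j, child in enumerate(_seed_sequence(rng).spawn(P)):
        sub = np.random.default_rng(child)
        w_j = np.sort(w + sub.uniform(-tau, tau, size=w.size))
        vprime = _pool(x, w_j, tau)
        samples[j], flag = _null_zeta_one(vprime, curve.v, curve.b)
        flagged += flag
    return NullDistribution(samples, "jitter", flagged)


def isi_shuffle_null(
    spikes, events, window=None, P: int = 100, rng=None
) -> NullDistribution:
    """Null distribution from inter-spike-interval shuffling.

    Each resample permutes the ISIs of the full spike train, rebuilds a
    surrogate train from the original first spike by cumulative summation,
    and evaluates the statistic against the *original* events.
    """
    if P < 2:
        raise ValueError("need at least 2 resamples")
    x = _spike_array(spikes)
    if x.size < 3:
        raise ValueError("ISI shuffling needs at least 3 spikes")
    w = _event_array(events)
    rel = pool_relative_spikes(x, w, window)
    curve = deviation_curve(rel)
    tau = rel.tau
    dt = np.diff(x)
    samples = np.empty(P)
    flagged = 0
    for j, child in enumerate(_seed_sequence(rng).spawn(P)):
        sub = np.random.default_rng(child)
        t0 = x[0] + np.concatenate(([0.0], np.cumsum(sub.permutation(dt))))
        vprime = _pool(t0, w, tau)
        samples[j], flag = _null_zeta_one(vprime, curve.v, curve.b)
        flagged += flag
    return NullDistribution(samples, "isi-shuffle", flagged)


# ---------------------------------------------------------------------------
# Significance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GumbelFit:
    """Method-of-moments Gumbel fit to the null samples."""

    mode_m: float
    beta: float
    gamma_const: float = EULER_GAMMA


def gumbel_significance(
    null: NullDistribution | np.ndarray, zeta_raw: float
) -> tuple[float, float, GumbelFit, bool]:
    """Gumbel p-value and z-scale corrected ZETA for an observed zeta_raw.

    beta = sqrt(6 Var(zeta'))/pi, m = mean(zeta') - beta*gamma;
    p = 1 - exp(-exp(-(zeta_r - m)/beta)); zeta = Phi^-1(1 - p/2).
    Returns (p, zeta_corrected, fit, saturated); ``saturated`` marks a p
    clamped to the smallest positive float (Gumbel tail underflow).
    """
    samples = null.zeta_samples if isinstance(null, NullDistribution) else np.asarray(null)
    var = float(np.var(samples, ddof=1))
    if var <= 0:
        raise ValueError("degenerate null: zero variance of resampled zeta")
    beta = math.sqrt(6.0 * var) / math.pi
    m = float(np.mean(samples)) - beta * EULER_GAMMA
    z = (zeta_raw - m) / beta
    # log-survival of the Gumbel CDF; -expm1 keeps precision for small p
    p = float(-np.expm1(-np.exp(-z)))
    saturated = False
    if p <= 0.0:
        p = float(np.finfo(float).tiny)
        saturated = True
    p = min(p, 1.0)
    zeta_corrected = float(stats.norm.isf(p / 2.0))
    return p, zeta_corrected, GumbelFit(m, beta), saturated


# ---------------------------------------------------------------------------
# The full test
# ---------------------------------------------------------------------------

@dataclass
class ZetaResult:
    zeta_raw: float
    zeta_time: float
    zeta_sign: int
    inverse_zeta_time: float
    p: float
    zeta_corrected: float
    null: NullDistribution | None
    curve: DeviationCurve | None
    gumbel: GumbelFit | None = None
    flags: list[str] = field(default_factory=list)


def zeta_test(
    spikes,
    events,
    window=None,
    P: int = 100,
    null_mode: NullMode = "jitter",
    rng=None,
) -> ZetaResult:
    """Run the full ZETA-test.

    Parameters
    ----------
    spikes, events
        A SpikeTrain / EventSeries or raw time arrays (seconds).
    window
        AnalysisWindow, duration in seconds, or None for the default
        (median onset-to-onset interval).
    P
        Number of null resamples (default 100).
    null_mode
        "jitter" (event-onset jittering, the reference construction) or
        "isi-shuffle" (inter-spike-interval shuffling variant).
    rng
        Seed / SeedSequence / Generator; resamples use substreams derived
        deterministically from it.
    """
    rel = pool_relative_spikes(spikes, events, window)
    if rel.is_empty:
        return ZetaResult(
            0.0, 0.0, 0, 0.0, 1.0, 0.0, None, None, None, flags=["no spikes"]
        )
    curve = deviation_curve(rel)
    zeta_raw, zeta_time, sign, inv_time = zeta_statistic(curve)
    if null_mode == "jitter":
        null = jitter_null(spikes, events, rel.tau, P=P, rng=rng)
    elif null_mode == "isi-shuffle":
        null = isi_shuffle_null(spikes, events, rel.tau, P=P, rng=rng)
    else:
        raise ValueError(f"unknown null mode {null_mode!r}")
    flags: list[str] = []
    if null.n_flagged:
        flags.append(f"{null.n_flagged} empty resamples")
    try:
        p, zeta_c, fit, saturated = gumbel_significance(null, zeta_raw)
    except ValueError:
        return ZetaResult(
            zeta_raw, zeta_time, sign, inv_time, 1.0, 0.0, null, curve,
            None, flags=flags + ["degenerate null"],
        )
    if saturated:
        flags.append("saturated")
    return ZetaResult(
        zeta_raw, zeta_time, sign, inv_time, p, zeta_c, null, curve, fit, flags
    )
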