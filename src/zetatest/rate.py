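"""Binless instantaneous firing rate (IFR) from multi-scale derivatives.

The local slope of the ZETA deviation curve ``d`` tracks deviations of the
firing rate from its mean. Averaging finite-difference slopes over a
logarithmic grid of timescales suppresses spike-level noise while
preserving sharp rate transients; rescaling the averaged derivative yields
a firing-rate estimate in Hz whose temporal resolution is limited only by
the spike density. Peak, onset (half-peak crossing) and trough latencies
are read off this rate curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import DeviationCurve, deviation_curve, pool_relative_spikes

__all__ = [
    "TimescaleGrid",
    "MultiScaleRate",
    "LatencyEstimate",
    "build_timescales",
    "multiscale_derivative",
    "instantaneous_rate",
    "latency_estimates",
    "instantaneous_firing_rate",
]


@dataclass(frozen=True)
class TimescaleGrid:
    """Logarithmic grid of derivative timescales t = base**p (seconds),
    with integer exponents p strictly inside (log_b 1e-3, log_b tau/10)."""

    base: float
    exponents: np.ndarray
    timescales: np.ndarray

    @property
    def S(self) -> int:
        return self.timescales.size


def build_timescales(tau: float, base: float = 1.5) -> TimescaleGrid:
    """Build the timescale grid for a window of duration ``tau``.

    Timescales span (1 ms, tau/10), exclusive at both ends; a smaller base
    gives a denser (slower, slightly more accurate) grid.
    """
    if base <= 1.0:
        raise ValueError("base must be > 1")
    lo = math.log(1e-3) / math.log(base)
    hi = math.log(tau / 10.0) / math.log(base)
    # Round to kill representation error before applying the strict bounds.
    lo, hi = round(lo, 9), round(hi, 9)
    p_min = int(math.floor(lo)) + 1
    p_max = int(math.ceil(hi)) - 1
    if p_max < p_min:
        raise ValueError("window too short for multi-scale grid")
    p = np.arange(p_min, p_max + 1)
    return TimescaleGrid(base, p, base ** p.astype(float))


@dataclass(frozen=True)
class MultiScaleRate:
    """Instantaneous firing rate sampled at the pooled spike times."""

    v: np.ndarray
    msd: np.ndarray        # multi-scale derivative m_i
    msd_mean: float        # ISI-weighted time average of m
    rate: np.ndarray       # r_i, Hz
    n: int
    q: int
    tau: float


def multiscale_derivative(curve: DeviationCurve, grid: TimescaleGrid) -> np.ndarray:
    """Average finite-difference slope of ``d`` over the timescale grid.

    For spike i and timescale t_k the slope is taken between the nearest
    spikes strictly outside [v_i - t_k/2, v_i + t_k/2]; indices clamp to
    the window edges when that interval leaves [0, tau].
    """
    v, d = curve.v, curve.d
    n = v.size
    if n < 3:
        raise ValueError("need at least 3 spike times for derivatives")
    msd = np.zeros(n)
    for t in grid.timescales:
        lo = v - t / 2.0
        hi = v + t / 2.0
        a = np.searchsorted(v, lo, side="left") - 1  # largest v < lo
        b = np.searchsorted(v, hi, side="right")     # smallest v > hi
        np.clip(a, 0, n - 1, out=a)
        np.clip(b, 0, n - 1, out=b)
        denom = v[b] - v[a]
        slope = np.zeros(n)
        ok = denom > 0
        slope[ok] = (d[b[ok]] - d[a[ok]]) / denom[ok]
        if not ok.all():
            # coincident endpoints: widen to the nearest distinct neighbors
            for i in np.flatnonzero(~ok):
                ai, bi = a[i], b[i]
                while ai > 0 and v[ai] == v[bi]:
                    ai -= 1
                while bi < n - 1 and v[bi] == v[ai]:
                    bi += 1
                if v[bi] > v[ai]:
                    slope[i] = (d[bi] - d[ai]) / (v[bi] - v[ai])
        msd += slope
    msd /= grid.S
    return msd


def instantaneous_rate(msd: np.ndarray, curve: DeviationCurve, q: int) -> MultiScaleRate:
    """Rescale the multi-scale derivative to a firing rate in Hz.

    r = n/(tau q) * (m + 1/tau) / (m_bar + 1/tau) with m_bar the trapezoid
    (ISI-weighted) time average of m, so the time average of r equals the
    mean rate n/(tau q) by construction.
    """
    v, tau = curve.v, curve.tau
    n = v.size
    m_bar = float(np.trapezoid(msd, v)) / tau
    denom = m_bar + 1.0 / tau
    if denom == 0:
        raise ValueError("degenerate rate normalization (m_bar == -1/tau)")
    rate = (n / (tau * q)) * (msd + 1.0 / tau) / denom
    return MultiScaleRate(v, msd, m_bar, rate, n, q, tau)


@dataclass(frozen=True)
class LatencyEstimate:
    """Response latencies read off the instantaneous rate curve (seconds)."""

    peak_time: float
    peak_rate: float
    onset_time: float
    trough_time: float
    flags: tuple[str, ...] = ()


def latency_estimates(rate: MultiScaleRate) -> LatencyEstimate:
    """Peak / onset / trough latencies from the rate curve.

    The onset is the time the half-peak level (midway between the curve's
    minimum and maximum) is last crossed from below before the peak — the
    half-maximal rise of the response peak. Ties in the extrema break to
    the earliest time.
    """
    r, v = rate.rate, rate.v
    i_peak = int(np.argmax(r))
    i_trough = int(np.argmin(r))
    r_max, r_min = float(r[i_peak]), float(r[i_trough])
    if r_max == r_min:
        nan = float("nan")
        return LatencyEstimate(nan, r_max, nan, nan, flags=("constant rate",))
    half = r_min + (r_max - r_min) / 2.0
    below = np.flatnonzero(r[:i_peak] < half)
    flags: tuple[str, ...] = ()
    if below.size:
        j = int(below[-1])
        # linear interpolation of the upward crossing between samples j, j+1
        dr = r[j + 1] - r[j]
        onset = float(v[j] + (half - r[j]) * (v[j + 1] - v[j]) / dr)
    else:
        onset = float(v[0])
        flags = ("no half-peak crossing before peak",)
    return LatencyEstimate(float(v[i_peak]), r_max, onset, float(v[i_trough]), flags)


def instantaneous_firing_rate(
    spikes, events, window=None, base: float = 1.5
) -> MultiScaleRate:
    """Convenience front end: pool spikes, build the deviation curve and the
    timescale grid, and return the instantaneous rate."""
    rel = pool_relative_spikes(spikes, events, window)
    curve = deviation_curve(rel)
    grid = build_timescales(rel.tau, base=base)
    msd = multiscale_derivative(curve, grid)
    return instantaneous_rate(msd, curve, rel.q)
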