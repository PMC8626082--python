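# Methods

## The ZETA statistic

Given a neuron's spike times `x` and event (stimulus-onset) times `w`, the
package asks whether spiking is time-locked to the events without binning
the data or choosing a timescale. Spikes are pooled into each event window
`(w_k, w_k + tau]` relative to its onset; two sentinel entries at 0 and
`tau` guarantee coverage of the full window. By default `tau` is the median
onset-to-onset interval. When the windows tile the recording (the usual
design) each spike appears exactly once; when windows overlap — which
happens for resampled, jittered onsets — a spike contributes to every
window that contains it. The per-window rule is essential: it keeps the
pooled relative-time density uniform for a stationary train regardless of
the event spacing, and therefore keeps the resampled null calibrated. An
assignment to the most recent onset only (with gaps between windows
discarded) makes the resampled relative-time distribution non-uniform and
drives the measured false-positive rate to zero.

With `v` the sorted pooled times (`n` entries including sentinels), the
empirical cumulative spike fraction is `g_i = i/n` and the linear baseline
expected for an unmodulated rate is `b_i = v_i/tau`. The deviation is
`delta = g - b`, and `d = delta - mean(delta)` is its mean-centered
version. Centering makes the multiset of `d` values invariant under a
circular shift of all event times (a shift only reorders `d`), so the
statistic does not depend on where the trial onsets are placed. The raw
statistic is `zeta_r = max|d|`; its time, sign, and the time of the most
extreme opposite-sign deviation are reported alongside. Ties in the argmax
break to the earliest time so latency annotations are reproducible.

## Null distribution and significance

The null is built by resampling. In the reference mode each event time is
independently displaced by a uniform offset on `[-tau, +tau]`, the spikes
are re-pooled, and the resampled cumulative fraction is linearly
interpolated back onto the original spike times `v` before subtracting the
original baseline `b`; the maximum absolute centered deviation is one null
sample `zeta'(j)`. The alternative mode shuffles the inter-spike intervals
of the whole train, rebuilds a surrogate train from the original first
spike, and evaluates it against the original events. One hundred resamples
are used by default. A resample in which no spike lands in any window
contributes `zeta' = 0` and is flagged.

Because `zeta_r` is a maximum, the null samples are summarized by a Gumbel
distribution fitted by the method of moments: scale
`beta = sqrt(6 Var(zeta'))/pi` and mode `m = mean(zeta') - beta*gamma`,
with `gamma ~ 0.5772` the Euler–Mascheroni constant (sample variance with
`ddof=1`). The p-value is the Gumbel survival value at `zeta_r`, computed
through `expm1` to keep precision in the far tail and clamped to the
smallest positive float (with a `saturated` flag) rather than ever
reporting exactly zero. The z-scale statistic is `Phi^-1(1 - p/2)`. For
i.i.d. uniform spikes the closed-form order statistics give
`Var(delta_i) = i(n-i+1)/((n+1)^2(n+2))` and the constant
`Var(d_i) = (n-1)/(12n(n+1))`; the test suite checks both, together with
the exact reordering property under circular shifts and the rank agreement
between the Gumbel p and the empirical percentile of `zeta_r` in the null
samples.

Randomness is controlled by a single seed: every stochastic operation
accepts an integer, `SeedSequence` or `Generator`, and per-resample
substreams are spawned deterministically from it, so results are
bit-reproducible.

## Instantaneous firing rate and latencies

The local slope of `d` tracks deviations of the firing rate from its mean.
Slopes are measured at every spike over a logarithmic grid of timescales
`t = 1.5**p` with integer exponents strictly inside
`(log_1.5 1e-3, log_1.5 tau/10)`; for spike `i` and timescale `t`, the
slope is taken between the nearest spikes strictly outside
`[v_i - t/2, v_i + t/2]` (indices clamp to the window edges when that
interval leaves `[0, tau]`; coincident endpoints widen to the nearest
distinct neighbors). Averaging over timescales suppresses spike-level
noise — long timescales pull toward zero, and short-timescale noise
averages out — while preserving sharp transients. The averaged derivative
`m` is bounded below by `-1/tau`; rescaling by
`r = n/(tau q) * (m + 1/tau)/(m_bar + 1/tau)`, with `m_bar` the trapezoid
(inter-spike-interval weighted) time average of `m`, yields a rate in Hz
whose time average equals the mean rate `n/(tau q)` exactly. The printed
form of the weighted average uses the interval `v_{i-1} - v_i`; the
positive difference is implemented, since a time-weighted mean requires
positive weights.

Latencies are read off `r`: the peak is the global maximum (earliest on
ties), the trough the global minimum within the window, and the onset is
the last upward crossing, before the peak, of the level halfway between
the curve's minimum and maximum (linearly interpolated between samples).
Half-peak is referenced to the curve's minimum rather than zero because
the rate floor inside a window is rarely exactly zero. A constant rate
yields flagged, undefined latencies.

Being a global argmax, the peak estimator has a small failure mode at the
hardest benchmark condition (wide peaks on a strong background, e.g.
sigma = 10 ms on 32 Hz): in a few percent of neurons a background
fluctuation edges out the true peak, producing a gross outlier while the
remaining errors stay unbiased with spread proportional to the peak width.
The latency benchmark therefore reports robust (median/MAD) error
summaries alongside the plain mean and SD.

## Baseline tests

- Paired mean-rate t-test between per-trial rates in a stimulus epoch and
  a non-overlapping baseline epoch (defaults 0–1 s and 1–1.5 s after
  onset). Zero-variance differences report p = 1 with an undefined
  statistic, a deliberate convention for screening pipelines.
- PSTH one-way ANOVA across bins with per-trial counts as replicates, at a
  fixed width or at the cost-minimizing width `argmin (2k̄ - v)/Δ²` (mean
  and biased variance of trial-mean bin counts), found by an iterative
  10-point grid refinement on `[1 ms, tau/2]` that stops when the bracket's
  relative span falls below 1e-3; the refined minimum is tested against a
  dense brute-force grid.
- A multi-scale ANOVA set on a base-2 grid of widths around 1/60 s
  (nineteen widths spanning 1/512th to 512 times the center), Bonferroni
  corrected over the widths actually run (widths too wide to give two bins
  inside the window are dropped with a warning).
- Renewal-process tests on 1 ms binned trial-averaged counts: a one-sample
  KS test against the analytic trial-averaged homogeneous-Poisson null
  (the null is discrete, so the KS distance is evaluated over the count
  atoms; the continuous asymptotic p-value is conservative, and a
  two-sample sampled variant is available behind a flag); a two-sample KS
  against pooled ISI-shuffled surrogate PSTHs; and Gumbel tests of the
  most extreme absolute deviation of the PSTH, or of its mean-centered
  cumulative sum, against the same surrogates.

## Simulators

All generators are bit-reproducible from `(params, seed)` and return
ground-truth modulation labels. Homogeneous-rate segments draw a Poisson
count per segment and place the spikes uniformly — the same point process
as consecutive exponential intervals, but vectorizable.

**Tuned Poisson.** Baseline rate `mu_base ~ Exp(mean 5 Hz)`; preferred rate
`mu_stim ~ Exp(mean mu_base + 20 Hz)`, so the population means are 5 and
25 Hz. The direction tuning is the sum of two von Mises lobes at the
preferred orientation and its opposite (`kappa ~ 5 + U(0,5)`), rescaled to
run from `mu_base` at the trough to `mu_stim` at the peak; twenty repeats
of eight directions with 1 s stimulus and 1 s inter-trial epochs.

**Rate/duration grid.** During the stimulus second the rate is
`(background + dHz)/T_r` for the first `T_r` seconds and zero afterwards,
conserving the expected stimulus spike count `background + dHz` for every
response duration; the inter-trial second runs at the background rate
(1 Hz). Default 100 trials per neuron.

**Bursting neurons.** A ~1 Hz single-spike Poisson process (rate
`Exp(mean 1)`) superimposed with a burst process. Burst onsets form a
Poisson process with intensity `R_b ~ |N|/20 + 1/80` at baseline (mean
inter-burst interval ~16–19 s) plus `R_t * VM(theta_p, kappa)` during
stimuli (`R_t ~ |N| + 1/4`, `theta_p ~ U(0, 2pi)`, `kappa ~ 5 + U(0,5)`),
putting the preferred-stimulus inter-burst interval near 0.8 s. Each burst
expands into spikes over a `Gamma(2k_dur, 0.5)` ms duration
(`k_dur ~ N(90, 10)`) with `Gamma(2k_isi, 0.5)` ms intra-burst intervals.
The intra-burst shape parameter is drawn as `k_isi ~ 0.5 + Exp(mean 1.1) ms`:
the conventional notation for this exponential is ambiguous between a
rate and a mean reading, and the two readings bracket the target
population firing-rate quartiles for this generator (responsive
6.7–19.7 Hz, unresponsive 6.9–20.7 Hz with a fixed ~6.8 s inter-burst
interval); the
scale is fixed once by least joint relative error against those four
printed percentiles (means of 1.1-1.2 ms are indistinguishable; 1.1 ms
is adopted). Non-positive
parameter draws are redrawn, never clamped. Trials are 20 repeats of 24
directions (1 s stimulus, 0.5 s inter-trial), and the burst and
single-spike processes superimpose independently.

**Peak-latency neurons.** A constant-rate background with one extra spike
added to a random half of all trials at `N(center, sigma^2)` after onset,
`center ~ U(90, 110) ms` per neuron.

**Null twins.** Event-unlocked copies for ROC negatives and calibration:
jittering displaces each onset independently by `U(-J, +J)` (default one
median onset-to-onset interval) leaving the spikes untouched; ISI
shuffling permutes each train's intervals leaving the events untouched.

## Benchmarks and problem sizes

ROC curves sweep the significance threshold over the pooled p-values; the
trapezoid AUC equals the Wilcoxon–Mann–Whitney rank statistic with ties
counted half, which the tests assert exactly. Inclusion rates carry
Clopper–Pearson 95% intervals.

Default benchmark sizes are chosen to make a full validation run complete
in minutes on one core: 250 neurons per class (480 trials, 100 resamples)
for the bursting power benchmark, 1000 event-unlocked tuned-Poisson
neurons for type-I calibration, 1000 responsive neurons for the
firing-rate percentile calibration, and 40 neurons per peak width (160
trials, 32 Hz background) for the latency benchmark. At these sizes the
AUC Monte-Carlo standard error is about 0.01–0.02 and the calibration
band at alpha = 0.05 is about ±1.5 percentage points.

Measured at these scales, the onset-jitter ZETA-test's false-positive
rate sits within the binomial band around 5%, and it discriminates
responsive from unresponsive bursting neurons with AUC ≈ 0.95. The
ISI-shuffle variant is strongly anticonservative on unresponsive bursty
neurons (shuffling destroys burst structure that onset jittering
preserves), which is exactly the mechanism that makes it the weaker of
the two variants; the mean-rate t-test discriminates this particular
generator's populations very strongly (AUC ≈ 0.96–0.98): with the burst
intensities above and 480 trials, nearly every responsive neuron carries
a detectable mean-rate difference, so the t-test is a strong competitor
on this benchmark even though it ignores spike timing entirely.

## Known limitations

- The Gumbel fit is an asymptotic summary of 100 resampled maxima; p-values
  below ~1e-4 are extrapolations beyond the resampling resolution (their
  rank order remains correct, as the oracle test verifies).
- The ISI-shuffle null assumes the unmodulated train is close to a renewal
  process; for strongly bursting cells it is anticonservative, and the
  onset-jitter null should be preferred.
- The IFR peak latency is a global argmax and can lock onto background
  fluctuations when the true peak's elevation approaches the background's
  extreme-value ceiling (see above).
- Events are treated as exchangeable; per-condition (label-wise) analyses
  are left to the caller by subsetting events.
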