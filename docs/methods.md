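# Methods

This note documents the models and procedures implemented in `adfc`,
the parameters that matter, the numerical choices made where the design
was open, and what the synthetic testbeds do and do not show.

## Controller model

The controller observes the instantaneous population firing rate FR(t)
— spikes per active electrode per second in a causal square window
(default 0.1 s, sometimes 0.2–0.5 s for slower cultures) — and filters
it with a damped harmonic oscillator

    ẍ + ω ẋ + ω² x = k · FR(t),    k = ω.

The output is ẋ, a band-passed representation of the population rhythm
around the natural frequency ω. Setting k = ω gives the transfer
function from FR to ẋ the value k·iω/(iω²) = 1 at resonance: unit gain
and zero phase for an oscillation at frequency ω, independent of the
period of the particular network. The actuation (stimulation-frequency)
signal is

    SF(t) = K ( ẋ(t − T/2) − ẋ(t) ),

which for a sinusoidal ẋ equals −2K·ẋ(t): maximal exactly at the
antiphase of the ongoing oscillation and proportional to its amplitude,
so stimulation self-limits as desynchronisation succeeds. A stimulus is
emitted when `t > t_last + 1/SF(t)`, restricted to
`sf_min < SF < sf_max` (defaults 1 and 20 Hz, the in vitro operating
range; the upper bound also reflects actuation latency and imposes a
refractory interval of 1/sf_max between stimuli).

**DFC vs aDFC.** DFC keeps T and ω at their operator-supplied initial
values. aDFC detects network bursts online — upward crossings of an FR
threshold (default 10 Hz) separated by at least a minimum interval
(default 0.1 s) — and at each burst re-estimates T as the median of the
last m = 3 inter-burst intervals, setting ω = 2π/T and the delay to
T/2. The median over a short history is a robust, online-computable
estimator; the history length m is configurable. The Poisson protocol
generates a homogeneous Poisson stimulus train at the mean rate of a
reference aDFC run; it is the open-loop control condition.

**Numerics.** The oscillator is advanced with the exact zero-order-hold
discretisation of the linear system (closed-form 2×2 matrix
exponential, recomputed whenever ω changes): the update is exact for
piecewise-constant input, unconditionally stable for any sample step,
and reproduces the analytic impulse response (decay ω/2, ringing
ω√3/2) to < 1e−3 relative error in the acceptance checks. A plain
first-order scheme would need a stability guard and would not reach
that accuracy at practical steps. The delayed sample ẋ(t − T/2) is
read from a growable history buffer with linear interpolation; history
before the start is zero, so the first half-period of a run has a
biased (small) actuation signal. When T is re-estimated the new delay
applies immediately at the current estimate. With `positive_only`
(used in silico, where only excitatory stimulation exists), negative
SF is clamped to zero. SF above `sf_max` is clipped rather than
suppressed: suppression would silence the controller exactly when the
oscillation is strongest, which contradicts the bound's stated purpose
(actuation latency); the behaviour is configurable.

## Activity metrics

**Firing rate.** Causal (trailing) windows aligned to the recording
start; only electrodes with mean rate > 0.1 Hz count as active, and the
rate is normalised per active electrode. Causal alignment matches the
controller's real-time constraint, so offline recomputation equals the
online trace up to a one-sample grid shift.

**χ synchrony.** Each active channel's spike train is convolved with a
50 ms square box and binarised into an occupancy signal V_i(t) on a
1 ms grid; then χ² = Var(mean_i V_i) / mean_i Var(V_i). Binarisation
measures the co-activation of electrodes regardless of how many spikes
each contributes per activation. χ (the square root) is reported, lying
in [0, 1] with the asynchronous-state threshold at 0.5; χ² is available
via `squared=True`. Boxes are half-open `[s − w/2, s + w/2)` so that
perfectly alternating channels tile time exactly and yield χ = 0; per
channel, Var(V) = p(1 − p) is computed from the occupancy fraction.
χ = 1 for identical trains and approaches 1/√N for N independent
channels. The 1 ms grid and the 50 ms box are configurable (the in
silico analyses use a 5 ms box, matching the model's roughly ten-fold
faster burst timescale).

**Oscillation intensity.** The mean-removed FR is analysed with a
Hann-windowed Welch PSD, segment length min(n/8, 2048) samples, 50%
overlap (recorded in output metadata). The fundamental is the PSD
maximum outside the DC band; the SNR is the ratio of fundamental-band
power to noise power in dB, where the DC band, the fundamental band and
six harmonic bands are excluded from the noise. Each excluded band
extends from its peak to the nearest flanking local minima (at least
±1 bin) — a fixed ±1 bin band undercounts the leakage of a Hann-tapered
line that falls between bins and would inflate the noise estimate by
several dB. Flat signals return NaN (no fundamental).

**Wavelet spectrogram.** Analytic Morlet CWT on log-spaced frequencies,
default 0.05–5 Hz, covering network-burst periods of roughly 0.2–20 s.
Used to visualise period drift and regime changes; the ridge (per-time
argmax) tracks the instantaneous burst frequency.

**Sliding windows.** Firing rate and χ in a moving window with step =
half the window width; the window width for state clustering is the
average duration of five periodic events (five median inter-burst
intervals), with a 10 s fallback for burst-free recordings.

## In silico testbed

All-to-all networks of Izhikevich neurons: regular-spiking excitatory
(a = 0.02, b = 0.2, c = −65, d = 8) and fast-spiking inhibitory
(a = 0.1, b = 0.2, c = −65, d = 2) cells, excitatory weights uniform on
[0, 0.5], inhibitory on [−1, 0], per-step Gaussian noise drive (SD 5
excitatory, 2 inhibitory), dt = 1 ms with two 0.5 ms half-updates of v.
The defaults are N = 1000 neurons with a randomly chosen pool of 100
stimulated neurons; a stimulus is an instantaneous +20 current for one
step (the model's current units are dimensionless). Design choices
where the reference recipe was open: self-connections are excluded
(configurable); weights are scaled by 1000/N so total synaptic input is
comparable across network sizes, letting the same weight-scale axis
span the same dynamical regimes at reduced N.

A closed-loop run simulates 500 ms of stabilisation (excluded from
metrics), 2000 ms of spontaneous activity (OFF) and 2000 ms under aDFC
(ON). The controller consumes the online population rate of all neurons
in a 10 ms trailing window — the in vitro 0.1 s window rescaled to the
model's faster bursts — with SF bounds likewise rescaled to 10–200 Hz
and gain K = 5, chosen once by pilot runs of the testbed (the in vitro
gains and thresholds were likewise tuned during pre-experiment
monitoring). The burst threshold is calibrated per simulation midway
between the median and peak OFF-segment firing rate, and the initial
period from the median OFF inter-burst interval.

The controllability sweep covers excitatory fraction × weight scale
with 5 independent seeds per cell, reporting mean OFF synchrony/firing
rate and the ON−OFF change. The scaled-down default grid —
frac_exc ∈ {0.6, 0.8, 0.9}, weight_scale ∈ {0.6, 1.0, 2.0} at N = 300 —
spans the three regimes seen at full size: sparse chaotic activity
(low/low), strong ordered bursting (high/high), and the intermediate
transition band where aDFC can desynchronise the network. The scaled
problem size keeps a full sweep under a minute; the regime ordering is
preserved (verified by the monotone-map acceptance check).

## Experiment analysis

Trials follow the OFF-ON-OFF design (three 5-minute segments in vitro;
arbitrary durations accepted). Fold changes normalise ON (and post-OFF)
metrics to the pre-stimulation baseline: ratios for synchrony and
firing rate, differences for the dB-scaled oscillation intensity. A
network is *controllable* when a one-way MANOVA (Wilks' lambda with
the F-approximation, exact for three groups) of the per-trial
normalised ON triplets across the three protocols gives p < 0.05; at
least three trials per protocol are required. The default response set
is the three headline metrics; the oscillation frequency can be added
via the input table. The MANOVA consumes fold changes (the normalised
ON values); raw ON metrics can be passed instead by constructing the
table directly.

Baseline dynamics are summarised by projecting z-scored (synchrony,
firing rate) pairs onto their first principal component, oriented to
load positively on firing rate. State clustering fits full-covariance
Gaussian mixtures with 1–4 components, 10 restarts each, selecting by
BIC; a cluster is an asynchronous state (AS) when its mean synchrony is
below 0.5 and its mean firing rate is below the network's average.
Time in AS is the percentage of sliding-window time labelled AS, with
windows assigned to segments by their centre.

## Synthetic data generator

The bursting generator emulates the statistical structure of cultured
hippocampal networks on MEAs: burst onsets on a period-T grid with
truncated Gaussian jitter, a rectangular within-burst rate envelope
(Poisson at the burst rate, default 50 Hz for 0.15 s), per-burst
channel participation, and Poisson background activity (default
0.5 Hz). Defaults (16 channels, T = 1 s, 2% jitter, 60 s) sit in the
middle of the 0.5–5 s burst-period range typical of such cultures.
Multi-stable recordings concatenate regimes with known dwell times and
return ground-truth labels; drifting-period recordings interpolate T
linearly between endpoints.

What the generator does *not* model: biophysical burst shapes
(rise/decay envelopes), electrode noise and detection artefacts,
inter-channel rate heterogeneity, refractoriness, and any feedback from
stimulation to activity (stimuli do not alter synthetic spike trains —
closed-loop effects are only testable in the Izhikevich testbed).
Passing metric and controller tests on this data therefore validates
algorithmic correctness and the direction of effects, not biological
effect sizes.

## Known limitations

* BIC-selected component counts on real (non-Gaussian) window-metric
  clouds tend to exceed the number of dynamical regimes — the strongly
  bursting state is not Gaussian in (FR, χ) — but the AS flagging rule
  is robust to this over-segmentation because sub-clusters of the
  synchronous state fail the AS criteria; component-count recovery is
  therefore guaranteed only for Gaussian-separable states.
* The online FR trace and offline recomputation differ by one sample at
  segment boundaries (causal-grid alignment).
* Hardware concerns — stimulus-pulse shaping, electrode routing and
  loop latency — are out of scope; schedules carry amplitudes as
  metadata only.
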