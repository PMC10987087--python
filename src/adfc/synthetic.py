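"""Synthetic spike-train generators emulating MEA culture dynamics.

Cultured hippocampal networks on microelectrode arrays self-organise
into quasiperiodic network bursting with periods in the 0.5-5 s range.
These generators reproduce that statistical structure — and its
asynchronous and drifting-period variants — so that metrics,
controllers and analyses can be exercised without any recorded data:

* :func:`generate_bursting` — jittered-period network bursts with
  rectangular rate envelopes over Poisson background activity;
* :func:`generate_multistable` — concatenated regimes with ground-truth
  state labels, for validating state clustering;
* :func:`generate_drifting_period` — burst period sweeping linearly
  between two values, the stress input that defeats non-adaptive DFC.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .types import SpikeTrainSet

__all__ = [
    "BurstingModel",
    "generate_bursting",
    "generate_multistable",
    "generate_drifting_period",
]


@dataclass
class BurstingModel:
    """Statistical description of a quasiperiodically bursting culture.

    Burst onsets occur every ``period`` seconds with Gaussian jitter of
    SD ``period_jitter``; during a burst of ``burst_duration`` seconds,
    each channel participates with probability ``participation`` and
    fires as a Poisson process at ``burst_rate`` Hz; between bursts all
    channels fire Poisson background at ``background_rate`` Hz.
    """

    n_channels: int = 16
    period: float = 1.0
    period_jitter: float = 0.02
    burst_duration: float = 0.15
    burst_rate: float = 50.0
    background_rate: float = 0.5
    participation: float = 1.0
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if min(self.burst_rate, self.background_rate, self.period_jitter) < 0:
            raise ValueError("rates and jitter must be nonnegative")
        if not (0 <= self.participation <= 1):
            raise ValueError("participation must be in [0, 1]")
        if self.period > 0 and not (0 < self.burst_duration < self.period):
            raise ValueError("burst duration must lie in (0, period)")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def _poisson_times(rng: np.random.Generator, rate: float, t0: float, t1: float) -> np.ndarray:
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def _burst_onsets(rng: np.random.Generator, period: float, jitter: float,
                  duration: float, t0: float = 0.0) -> np.ndarray:
    """Jittered onset grid; jitter truncated at ±period/3 to keep order."""
    if period <= 0:
        return np.empty(0)
    base = np.arange(t0 + period / 2.0, t0 + duration, period)
    if jitter > 0:
        cap = period / 3.0
        base = base + np.clip(rng.normal(0.0, jitter, size=base.size), -cap, cap)
    return base


def _spikes_from_onsets(
    rng: np.random.Generator, model: BurstingModel, onsets: np.ndarray,
    t0: float, t1: float,
) -> list[np.ndarray]:
    trains: list[np.ndarray] = []
    for _ in range(model.n_channels):
        parts = [_poisson_times(rng, model.background_rate, t0, t1)]
        for onset in onsets:
            if rng.random() <= model.participation:
                end = min(onset + model.burst_duration, t1)
                parts.append(_poisson_times(rng, model.burst_rate, onset, end))
        train = np.sort(np.concatenate(parts))
        trains.append(train[(train >= t0) & (train <= t1)])
    return trains


def generate_bursting(model: BurstingModel) -> SpikeTrainSet:
    """Quasiperiodic network-bursting spike trains.

    Reproducible under ``model.seed``. With zero jitter, zero background
    and full participation, burst onsets are recovered exactly by FR
    threshold crossing."""
    rng = np.random.default_rng(model.seed)
    onsets = _burst_onsets(rng, model.period, model.period_jitter, model.duration)
    trains = _spikes_from_onsets(rng, model, onsets, 0.0, model.duration)
    active = np.ones(model.n_channels, dtype=bool)
    return SpikeTrainSet(list(range(model.n_channels)), trains, 0.0, model.duration,
                         active_mask=active)


def generate_multistable(
    models: list[tuple[BurstingModel, float]], seed: int | None = None
) -> tuple[SpikeTrainSet, list[tuple[float, float, int]]]:
    """Concatenate firing regimes with stated dwell times.

    ``models`` is a sequence of (regime model, dwell duration s); regime
    index cycles through the sequence in order. Returns the spike trains
    plus ground-truth labels as (t0, t1, model_index) intervals that
    exactly partition the timeline.
    """
    if len(models) < 2:
        raise ValueError("need at least two regimes")
    n_channels = models[0][0].n_channels
    if any(m.n_channels != n_channels for m, _ in models):
        raise ValueError("all regimes must share the channel count")
    rng = np.random.default_rng(models[0][0].seed if seed is None else seed)
    t = 0.0
    labels: list[tuple[float, float, int]] = []
    per_channel: list[list[np.ndarray]] = [[] for _ in range(n_channels)]
    for idx, (model, dwell) in enumerate(models):
        if dwell <= 0:
            raise ValueError("dwell durations must be positive")
        local = replace(model, duration=dwell)
        onsets = _burst_onsets(rng, local.period, local.period_jitter, dwell, t0=t) \
            if local.period > 0 else np.empty(0)
        trains = _spikes_from_onsets(rng, local, onsets, t, t + dwell)
        for ch in range(n_channels):
            per_channel[ch].append(trains[ch])
        labels.append((t, t + dwell, idx))
        t += dwell
    trains = [np.sort(np.concatenate(parts)) for parts in per_channel]
    sts = SpikeTrainSet(list(range(n_channels)), trains, 0.0, t,
                        active_mask=np.ones(n_channels, dtype=bool))
    return sts, labels


def generate_drifting_period(
    T_start: float,
    T_end: float,
    duration: float,
    model: BurstingModel | None = None,
) -> SpikeTrainSet:
    """Bursting whose period interpolates linearly from T_start to T_end.

    Onset spacing follows the instantaneous period T(t) = T_start +
    (T_end − T_start)·t/duration. Other burst statistics come from
    ``model`` (its own period/duration fields are ignored).
    """
    if T_start <= 0 or T_end <= 0:
        raise ValueError("periods must be positive")
    base = model if model is not None else BurstingModel()
    rng = np.random.default_rng(base.seed)
    onsets = []
    t = min(T_start, T_end) / 2.0
    while t < duration:
        onsets.append(t)
        T_here = T_start + (T_end - T_start) * t / duration
        jitter = float(np.clip(rng.normal(0.0, base.period_jitter), -T_here / 3, T_here / 3)) \
            if base.period_jitter > 0 else 0.0
        t += T_here + jitter
    onsets = np.asarray(onsets)
    local = replace(base, duration=duration,
                    burst_duration=min(base.burst_duration, 0.8 * min(T_start, T_end)))
    trains = _spikes_from_onsets(rng, local, onsets, 0.0, duration)
    return SpikeTrainSet(list(range(base.n_channels)), trains, 0.0, duration,
                         active_mask=np.ones(base.n_channels, dtype=bool))
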