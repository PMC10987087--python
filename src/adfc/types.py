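"""Core containers shared across the package.

All times are in seconds unless a field name says otherwise. A
:class:`SpikeTrainSet` holds per-channel spike timestamps and is the
universal input; every metric, controller and analysis consumes either a
``SpikeTrainSet`` or the :class:`FiringRateSignal` derived from one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SpikeTrainSet",
    "FiringRateSignal",
    "BurstEvents",
    "MetricsTriplet",
    "StimulationSchedule",
]

#: Electrodes with a mean rate above this (Hz) count as active.
DEFAULT_ACTIVITY_THRESHOLD_HZ = 0.1


@dataclass
class SpikeTrainSet:
    """Per-channel spike timestamps over a recording window.

    Parameters
    ----------
    channels
        Channel identifiers (electrode labels or neuron indices).
    spikes
        One nondecreasing array of spike times (s) per channel.
    t_start, t_end
        Recording window; all spikes must fall inside it.
    active_mask
        Per-channel activity flag. If omitted it is computed as
        mean rate > 0.1 Hz, mirroring the active-electrode selection
        used for MEA recordings.
    """

    channels: Sequence
    spikes: Sequence[np.ndarray]
    t_start: float
    t_end: float
    active_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError(f"t_end ({self.t_end}) must exceed t_start ({self.t_start})")
        if len(self.channels) != len(self.spikes):
            raise ValueError("channels and spikes must have equal length")
        self.spikes = [np.asarray(s, dtype=float) for s in self.spikes]
        for ch, s in zip(self.channels, self.spikes):
            if s.size and (np.any(np.diff(s) < 0)):
                raise ValueError(f"channel {ch}: spike times must be nondecreasing")
            if s.size and (s[0] < self.t_start - 1e-12 or s[-1] > self.t_end + 1e-12):
                raise ValueError(f"channel {ch}: spikes outside [t_start, t_end]")
        if self.active_mask is None:
            self.active_mask = self.compute_active_mask()
        else:
            self.active_mask = np.asarray(self.active_mask, dtype=bool)
            if self.active_mask.shape != (len(self.channels),):
                raise ValueError("active_mask must have one flag per channel")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_active(self) -> int:
        return int(np.sum(self.active_mask))

    def compute_active_mask(self, threshold_hz: float = DEFAULT_ACTIVITY_THRESHOLD_HZ) -> np.ndarray:
        """Flag channels whose mean firing rate exceeds ``threshold_hz``."""
        rates = np.array([s.size / self.duration for s in self.spikes])
        return rates > threshold_hz

    def active_spikes(self) -> list[np.ndarray]:
        """Spike arrays of active channels only."""
        return [s for s, a in zip(self.spikes, self.active_mask) if a]

    def slice(self, t0: float, t1: float, *, rebase: bool = False) -> "SpikeTrainSet":
        """Restrict to the window [t0, t1], keeping the parent active mask.

        With ``rebase=True`` times are shifted so the slice starts at 0.
        """
        if not (self.t_start - 1e-9 <= t0 < t1 <= self.t_end + 1e-9):
            raise ValueError(f"slice [{t0}, {t1}] outside recording [{self.t_start}, {self.t_end}]")
        shift = t0 if rebase else 0.0
        out = [s[(s >= t0) & (s <= t1)] - shift for s in self.spikes]
        return SpikeTrainSet(self.channels, out, t0 - shift, t1 - shift,
                             active_mask=self.active_mask.copy())

    def total_spike_count(self, active_only: bool = True) -> int:
        trains = self.active_spikes() if active_only else self.spikes
        return int(sum(s.size for s in trains))


@dataclass
class FiringRateSignal:
    """Uniformly sampled instantaneous population firing rate.

    ``values[i]`` is the rate (spikes per active electrode per second) in
    the causal window ``(t0 + i*dt - window, t0 + i*dt]``.
    """

    values: np.ndarray
    dt: float
    window: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.values.size and np.min(self.values) < 0:
            raise ValueError("firing rate cannot be negative")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) * self.dt

    @property
    def duration(self) -> float:
        return self.values.size * self.dt

    @property
    def fs(self) -> float:
        """Sampling frequency in Hz."""
        return 1.0 / self.dt


@dataclass
class BurstEvents:
    """Network-burst (synchronous event) timestamps from FR threshold crossings."""

    times: np.ndarray
    threshold: float
    min_interval: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1:
            gaps = np.diff(self.times)
            if np.any(gaps < self.min_interval - 1e-12):
                raise ValueError("burst events violate the minimum-interval rule")

    @property
    def n(self) -> int:
        return self.times.size

    def intervals(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass
class MetricsTriplet:
    """The headline activity descriptors of one recording segment.

    synchrony is the χ variance-ratio measure in [0, 1]; firing_rate is the
    average spikes per active electrode per second; oscillation_intensity is
    the SNR (dB) of the fundamental peak of the FR power spectrum; and
    oscillation_frequency is that fundamental (Hz, NaN when no peak exists).
    """

    synchrony: float
    firing_rate: float
    oscillation_intensity: float
    oscillation_frequency: float

    def as_dict(self) -> dict:
        return {
            "synchrony": self.synchrony,
            "firing_rate_hz": self.firing_rate,
            "oscillation_snr_db": self.oscillation_intensity,
            "fundamental_hz": self.oscillation_frequency,
        }


@dataclass
class StimulationSchedule:
    """Ordered stimulus times produced by a control protocol."""

    times: np.ndarray
    amplitude: np.ndarray | float = 1.0
    protocol: str = "DFC"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("stimulus times must be strictly increasing")
        if np.isscalar(self.amplitude):
            self.amplitude = np.full(self.times.size, float(self.amplitude))
        else:
            self.amplitude = np.asarray(self.amplitude, dtype=float)
            if self.amplitude.shape != self.times.shape:
                raise ValueError("amplitude must be scalar or match times")

    @property
    def n(self) -> int:
        return self.times.size

    def mean_frequency(self, duration: float) -> float:
        """Average stimulation frequency (Hz) over ``duration`` seconds."""
        if duration <= 0:
            raise ValueError("duration must be positive")
        return self.times.size / duration
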