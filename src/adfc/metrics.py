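"""Activity descriptors for population spike trains.

Implements the quantities used to characterise network dynamics and to
drive the closed-loop controllers:

* instantaneous population firing rate (causal square moving window),
* network-burst detection by threshold crossing,
* the χ variance-ratio synchrony measure on binarised electrode-occupancy
  signals,
* oscillation intensity as the SNR (dB) of the fundamental peak of the
  Welch power spectrum of the firing rate,
* a continuous-wavelet spectrogram of the firing rate,
* sliding-window firing-rate / synchrony traces for state analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sp_signal

from .types import BurstEvents, FiringRateSignal, MetricsTriplet, SpikeTrainSet

__all__ = [
    "compute_instantaneous_firing_rate",
    "detect_network_bursts",
    "compute_synchrony",
    "compute_oscillation_intensity",
    "average_firing_rate",
    "compute_wavelet_spectrogram",
    "sliding_window_metrics",
    "compute_metrics",
    "SilentRecordingError",
]

#: Grid on which electrode-occupancy signals are binarised (s).
OCCUPANCY_GRID_DT = 0.001
#: Width of the square box convolved with each spike train for χ (s).
DEFAULT_BOX_WIDTH = 0.05


class SilentRecordingError(ValueError):
    """Raised when a metric is undefined because every channel is silent."""


# ---------------------------------------------------------------------------
# Instantaneous firing rate and network bursts
# ---------------------------------------------------------------------------

def compute_instantaneous_firing_rate(
    spikes: SpikeTrainSet, window: float = 0.1, dt: float = 0.01
) -> FiringRateSignal:
    """Population firing rate in a causal square moving window.

    At each sample time ``t`` (grid starting at ``t_start``) the value is
    the number of spikes from active channels in ``(t - window, t]``
    divided by ``n_active * window`` — spikes per active electrode per
    second.
    """
    if window < dt:
        raise ValueError(f"window ({window}) must be >= dt ({dt})")
    n_active = spikes.n_active
    if n_active == 0:
        raise ValueError("no active channels: firing rate undefined")
    n_samples = int(np.floor(spikes.duration / dt)) + 1
    t = spikes.t_start + np.arange(n_samples) * dt
    trains = spikes.active_spikes()
    if any(s.size for s in trains):
        merged = np.sort(np.concatenate([s for s in trains if s.size]))
        # half-open (t - window, t] so a spike is counted exactly while the
        # trailing window covers it
        counts = np.searchsorted(merged, t, side="right") - np.searchsorted(
            merged, t - window, side="right"
        )
    else:
        counts = np.zeros(n_samples)
    values = counts / (n_active * window)
    return FiringRateSignal(values=values, dt=dt, window=window, t0=spikes.t_start)


def detect_network_bursts(
    fr: FiringRateSignal, threshold: float = 10.0, min_interval: float = 0.1
) -> BurstEvents:
    """Network bursts as upward threshold crossings of the FR signal.

    One event is emitted per upward crossing; crossings closer than
    ``min_interval`` to the previous accepted event are discarded.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_interval < 0:
        raise ValueError("min_interval cannot be negative")
    above = fr.values >= threshold
    # upward crossings; a suprathreshold first sample counts as a crossing
    crossings = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    times = fr.t0 + crossings * fr.dt
    accepted: list[float] = []
    for t in times:
        if not accepted or t - accepted[-1] >= min_interval:
            accepted.append(t)
    return BurstEvents(np.asarray(accepted), threshold=threshold, min_interval=min_interval)


# ---------------------------------------------------------------------------
# χ synchrony
# ---------------------------------------------------------------------------

def _occupancy_edges(train: np.ndarray, t0: float, t1: float, box_width: float,
                     grid_dt: float, n_grid: int) -> np.ndarray:
    """Per-sample occupancy of one channel on the analysis grid.

    A sample at ``t0 + j*grid_dt`` is occupied iff it falls inside the
    half-open box ``[s - w/2, s + w/2)`` of any spike ``s``. Half-open
    boxes make perfectly alternating channels tile time exactly.
    """
    occ = np.zeros(n_grid + 1, dtype=np.int32)
    if train.size == 0:
        return occ[:-1].astype(bool)
    half = box_width / 2.0
    lo = np.clip(np.ceil((train - half - t0) / grid_dt - 1e-9), 0, n_grid).astype(np.int64)
    hi = np.clip(np.ceil((train + half - t0) / grid_dt - 1e-9), 0, n_grid).astype(np.int64)
    np.add.at(occ, lo, 1)
    np.add.at(occ, hi, -1)
    return (np.cumsum(occ[:-1]) > 0)


def compute_synchrony(
    spikes: SpikeTrainSet,
    box_width: float = DEFAULT_BOX_WIDTH,
    grid_dt: float = OCCUPANCY_GRID_DT,
    *,
    squared: bool = False,
) -> float:
    """χ variance-ratio synchrony of the binarised occupancy signals.

    Each active channel's spike train is convolved with a square box of
    ``box_width`` seconds and binarised into an occupancy signal
    ``V_i(t)`` on a fixed ``grid_dt`` grid. Then

        χ² = Var( mean_i V_i(t) ) / mean_i Var( V_i(t) )

    χ (the square root, in [0, 1]) is returned by default; ``squared=True``
    returns χ². χ = 1 for identical trains, and tends to ``1/sqrt(N)`` for
    N independent channels.

    Raises
    ------
    SilentRecordingError
        If every active channel has zero occupancy variance (e.g. all
        silent), which leaves χ undefined.
    """
    if spikes.n_active < 2:
        raise ValueError("synchrony requires at least 2 active channels")
    if spikes.duration <= box_width:
        raise ValueError("recording must be longer than box_width")
    n_grid = int(np.floor(spikes.duration / grid_dt))
    trains = spikes.active_spikes()
    total = np.zeros(n_grid, dtype=np.float64)
    var_sum = 0.0
    for train in trains:
        occ = _occupancy_edges(train, spikes.t_start, spikes.t_end, box_width, grid_dt, n_grid)
        total += occ
        p = occ.mean()
        var_sum += p * (1.0 - p)  # binary signal: Var = p(1-p)
    n = len(trains)
    mean_var = var_sum / n
    if mean_var == 0.0:
        raise SilentRecordingError("all occupancy signals are constant; χ undefined")
    mean_signal = total / n
    chi2 = float(np.var(mean_signal) / mean_var)
    return chi2 if squared else float(np.sqrt(max(chi2, 0.0)))


# ---------------------------------------------------------------------------
# Oscillation intensity (PSD SNR)
# ---------------------------------------------------------------------------

def _band_extent(psd: np.ndarray, peak: int, max_half: int | None = None) -> tuple[int, int]:
    """Extent [lo, hi] of a spectral peak: walk to the nearest local minima.

    Mirrors the peak-extent bookkeeping of the classic SNR routine: the
    band reaches from the peak down to the first bin where the PSD stops
    decreasing on each side (at least ±1 bin).
    """
    lo = peak
    while lo > 0 and psd[lo - 1] < psd[lo]:
        lo -= 1
        if max_half is not None and peak - lo >= max_half:
            break
    hi = peak
    while hi < psd.size - 1 and psd[hi + 1] < psd[hi]:
        hi += 1
        if max_half is not None and hi - peak >= max_half:
            break
    lo = min(lo, peak - 1) if peak > 0 else lo
    hi = max(hi, peak + 1) if peak < psd.size - 1 else hi
    return max(lo, 0), min(hi, psd.size - 1)


def compute_oscillation_intensity(
    fr: FiringRateSignal,
    n_harmonics: int = 6,
    nperseg: int | None = None,
) -> tuple[float, float]:
    """SNR (dB) of the fundamental oscillation in the FR power spectrum.

    The mean-removed FR is analysed with a Hann-windowed Welch PSD
    (segment length ``min(n/8, 2048)`` samples, 50% overlap, unless
    ``nperseg`` overrides it). The fundamental is the PSD maximum with DC
    excluded; the SNR is ``10*log10(P_fundamental / P_noise)`` where the
    noise excludes DC, the fundamental band and ``n_harmonics`` harmonic
    bands, each extending to the local minima flanking its peak.

    Returns ``(snr_db, fundamental_hz)``; ``(nan, nan)`` for a flat
    signal with no spectral peak.
    """
    x = fr.values - np.mean(fr.values)
    if nperseg is None:
        nperseg = int(min(x.size // 8, 2048))
    if nperseg < 8 or x.size < 2 * nperseg:
        raise ValueError("signal too short for a two-segment Welch estimate")
    if not np.any(np.abs(x) > 1e-300):
        return (float("nan"), float("nan"))
    freqs, psd = sp_signal.welch(
        x, fs=fr.fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, detrend=False
    )
    # DC band: from 0 up to its local minimum
    _, dc_hi = _band_extent(psd, 0)
    if dc_hi >= psd.size - 1:
        return (float("nan"), float("nan"))
    peak = dc_hi + 1 + int(np.argmax(psd[dc_hi + 1:]))
    f0 = float(freqs[peak])
    excluded = np.zeros(psd.size, dtype=bool)
    excluded[: dc_hi + 1] = True
    sig_lo, sig_hi = _band_extent(psd, peak)
    signal_power = float(np.sum(psd[sig_lo: sig_hi + 1]))
    excluded[sig_lo: sig_hi + 1] = True
    df = freqs[1] - freqs[0]
    for h in range(2, n_harmonics + 2):
        hbin = int(round(h * f0 / df))
        if hbin >= psd.size:
            break
        # re-centre on the local max within ±1 bin (harmonics drift slightly)
        lo0, hi0 = max(hbin - 1, 0), min(hbin + 1, psd.size - 1)
        hpeak = lo0 + int(np.argmax(psd[lo0: hi0 + 1]))
        hlo, hhi = _band_extent(psd, hpeak)
        excluded[hlo: hhi + 1] = True
    noise = psd[~excluded]
    if noise.size == 0 or np.sum(noise) <= 0:
        return (float("inf"), f0)
    # estimate total noise power over the full band, interpolating across
    # the excluded regions at the mean noise level
    noise_power = float(np.mean(noise) * psd.size)
    snr_db = 10.0 * np.log10(signal_power / noise_power)
    return (float(snr_db), f0)


# ---------------------------------------------------------------------------
# Average firing rate, wavelet spectrogram, sliding windows
# ---------------------------------------------------------------------------

def average_firing_rate(spikes: SpikeTrainSet) -> float:
    """Average spikes per active electrode per second over the recording."""
    if spikes.duration <= 0:
        raise ValueError("recording duration must be positive")
    n_active = spikes.n_active
    if n_active == 0:
        return 0.0
    return spikes.total_spike_count() / (n_active * spikes.duration)


@dataclass
class WaveletSpectrogram:
    """|CWT| magnitude over time x frequency of a firing-rate signal."""

    times: np.ndarray
    frequencies: np.ndarray
    magnitude: np.ndarray  # shape (n_freqs, n_times)

    def ridge(self) -> np.ndarray:
        """Frequency of the per-time magnitude maximum (Hz)."""
        return self.frequencies[np.argmax(self.magnitude, axis=0)]


def compute_wavelet_spectrogram(
    fr: FiringRateSignal,
    freq_range: tuple[float, float] = (0.05, 5.0),
    n_freqs: int = 64,
    wavelet: str = "cmor1.5-1.0",
) -> WaveletSpectrogram:
    """Continuous wavelet transform magnitude of the mean-removed FR.

    Uses an analytic Morlet wavelet on logarithmically spaced frequencies
    covering ``freq_range`` (default 0.05-5 Hz, spanning network-burst
    periods of roughly 0.2-20 s). A periodic FR produces a ridge at its
    fundamental frequency.
    """
    f_lo, f_hi = freq_range
    nyquist = fr.fs / 2.0
    if not (0 < f_lo < f_hi <= nyquist):
        raise ValueError(f"freq_range must satisfy 0 < lo < hi <= Nyquist ({nyquist} Hz)")
    freqs = np.geomspace(f_lo, f_hi, n_freqs)
    scales = pywt.frequency2scale(wavelet, freqs * fr.dt)
    coef, actual = pywt.cwt(fr.values - np.mean(fr.values), scales, wavelet,
                            sampling_period=fr.dt)
    return WaveletSpectrogram(times=fr.times, frequencies=actual, magnitude=np.abs(coef))


def sliding_window_metrics(
    spikes: SpikeTrainSet,
    window: float,
    step: float | None = None,
    box_width: float = DEFAULT_BOX_WIDTH,
):
    """Firing rate and χ synchrony in a moving window.

    The step defaults to half the window width. Returns a pandas
    DataFrame with columns ``t`` (window centre), ``firing_rate`` and
    ``synchrony`` (NaN where χ is undefined, e.g. a silent window).
    """
    import pandas as pd

    if step is None:
        step = window / 2.0
    if step <= 0 or window <= 0:
        raise ValueError("window and step must be positive")
    if window > spikes.duration + 1e-9:
        raise ValueError("window exceeds recording duration")
    rows = []
    t0 = spikes.t_start
    while t0 + window <= spikes.t_end + 1e-9:
        t1 = min(t0 + window, spikes.t_end)
        chunk = spikes.slice(t0, t1)
        try:
            chi = compute_synchrony(chunk, box_width=box_width)
        except (SilentRecordingError, ValueError):
            chi = float("nan")
        rows.append({"t": 0.5 * (t0 + t1), "firing_rate": average_firing_rate(chunk),
                     "synchrony": chi})
        t0 += step
    return pd.DataFrame(rows)


def compute_metrics(
    spikes: SpikeTrainSet,
    fr_window: float = 0.1,
    fr_dt: float = 0.01,
    box_width: float = DEFAULT_BOX_WIDTH,
) -> MetricsTriplet:
    """The full descriptor triplet (plus fundamental) for one segment."""
    fr = compute_instantaneous_firing_rate(spikes, window=fr_window, dt=fr_dt)
    try:
        chi = compute_synchrony(spikes, box_width=box_width)
    except SilentRecordingError:
        chi = float("nan")
    try:
        snr_db, f0 = compute_oscillation_intensity(fr)
    except ValueError:
        snr_db, f0 = float("nan"), float("nan")
    return MetricsTriplet(
        synchrony=chi,
        firing_rate=average_firing_rate(spikes),
        oscillation_intensity=snr_db,
        oscillation_frequency=f0,
    )
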