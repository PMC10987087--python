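"""Unit and property tests for the activity metrics."""

import numpy as np
import pytest

from adfc import (
    FiringRateSignal,
    SilentRecordingError,
    SpikeTrainSet,
    average_firing_rate,
    compute_instantaneous_firing_rate,
    compute_oscillation_intensity,
    compute_synchrony,
    compute_wavelet_spectrogram,
    detect_network_bursts,
    sliding_window_metrics,
)


def _sts(trains, t0=0.0, t1=10.0):
    n = len(trains)
    return SpikeTrainSet(list(range(n)), [np.asarray(t, float) for t in trains],
                         t0, t1, active_mask=np.ones(n, dtype=bool))


class TestInstantaneousFiringRate:
    def test_single_spike_gives_rate_inverse_window(self):
        sts = _sts([[0.05]], t1=1.0)
        fr = compute_instantaneous_firing_rate(sts, window=0.1, dt=0.01)
        assert fr.values.max() == pytest.approx(10.0)  # 1 spike / (1 el x 0.1 s)
        # rate is 10 Hz exactly while the trailing window covers the spike
        # (the number of covering samples may vary by one at float boundaries)
        assert set(np.unique(fr.values)) == {0.0, 10.0}
        assert np.sum(fr.values == 10.0) in (10, 11)
        covered = (fr.times >= 0.05) & (fr.times <= 0.15)
        assert np.all(fr.values[~covered] == 0.0)

    def test_simultaneous_spikes_normalised_per_electrode(self):
        sts = _sts([[0.5], [0.5]], t1=1.0)
        fr = compute_instantaneous_firing_rate(sts, window=0.1, dt=0.01)
        assert fr.values.max() == pytest.approx(10.0)  # 2 / (2 x 0.1)

    def test_empty_recording_is_zero(self):
        sts = _sts([[]], t1=1.0)
        fr = compute_instantaneous_firing_rate(sts, window=0.1, dt=0.01)
        assert np.all(fr.values == 0.0)

    def test_window_smaller_than_dt_rejected(self):
        sts = _sts([[0.5]], t1=1.0)
        with pytest.raises(ValueError):
            compute_instantaneous_firing_rate(sts, window=0.001, dt=0.01)

    def test_no_active_channels_rejected(self):
        sts = SpikeTrainSet([0], [np.array([0.5])], 0.0, 1.0,
                            active_mask=np.array([False]))
        with pytest.raises(ValueError):
            compute_instantaneous_firing_rate(sts)

    def test_time_average_matches_average_firing_rate(self, bursting_spikes):
        fr = compute_instantaneous_firing_rate(bursting_spikes, window=0.1, dt=0.01)
        avg = average_firing_rate(bursting_spikes)
        # agreement up to edge effects of the trailing window
        assert fr.values.mean() == pytest.approx(avg, rel=0.02)


class TestNetworkBursts:
    def test_subthreshold_signal_has_no_events(self):
        fr = FiringRateSignal(np.full(100, 5.0), dt=0.01, window=0.1)
        assert detect_network_bursts(fr, threshold=10.0).n == 0

    def test_isolated_peaks_detected_at_crossings(self):
        values = np.zeros(300)
        values[100:105] = 20.0
        values[200:205] = 20.0
        fr = FiringRateSignal(values, dt=0.01, window=0.1)
        ev = detect_network_bursts(fr, threshold=10.0, min_interval=0.1)
        assert ev.n == 2
        np.testing.assert_allclose(ev.times, [1.0, 2.0])

    def test_close_crossings_suppressed_by_min_interval(self):
        values = np.zeros(100)
        values[10] = 20.0
        values[15] = 20.0  # 0.05 s later
        fr = FiringRateSignal(values, dt=0.01, window=0.1)
        assert detect_network_bursts(fr, threshold=10.0, min_interval=0.1).n == 1
        assert detect_network_bursts(fr, threshold=10.0, min_interval=0.01).n == 2

    @pytest.mark.parametrize("thr_pair", [(5.0, 10.0), (10.0, 20.0)])
    def test_burst_count_nonincreasing_in_threshold(self, bursting_spikes, thr_pair):
        fr = compute_instantaneous_firing_rate(bursting_spikes)
        lo, hi = thr_pair
        assert detect_network_bursts(fr, hi).n <= detect_network_bursts(fr, lo).n

    def test_burst_count_nonincreasing_in_min_interval(self, bursting_spikes):
        fr = compute_instantaneous_firing_rate(bursting_spikes)
        counts = [detect_network_bursts(fr, 10.0, mi).n for mi in (0.0, 0.1, 0.5, 2.0)]
        assert counts == sorted(counts, reverse=True)


class TestSynchrony:
    def test_identical_trains_give_unity(self):
        train = np.sort(np.random.default_rng(0).uniform(0, 20, 40))
        sts = _sts([train] * 4, t1=20.0)
        assert compute_synchrony(sts) == pytest.approx(1.0, abs=1e-12)

    def test_alternating_channels_give_zero(self):
        # two channels whose 50 ms boxes tile time exactly in antiphase
        w = 0.05
        a, b = [], []
        for blk in range(0, 20, 2):
            a.extend(np.arange(blk + w / 2, blk + 1, w))
            b.extend(np.arange(blk + 1 + w / 2, blk + 2, w))
        sts = _sts([a, b], t1=20.0)
        assert compute_synchrony(sts) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [4, 16, 64])
    def test_independent_trains_scale_inverse_sqrt_n(self, n):
        # E[chi^2] = 1/N for independent equal-variance occupancy signals
        vals = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            trains = [np.sort(rng.uniform(0, 100, rng.poisson(200))) for _ in range(n)]
            vals.append(compute_synchrony(_sts(trains, t1=100.0)))
        assert np.mean(vals) == pytest.approx(1.0 / np.sqrt(n), rel=0.15)

    def test_invariant_to_relabelling_and_time_shift(self, bursting_spikes):
        chi = compute_synchrony(bursting_spikes)
        perm = np.random.default_rng(1).permutation(bursting_spikes.n_channels)
        relabeled = SpikeTrainSet(
            [bursting_spikes.channels[i] for i in perm],
            [bursting_spikes.spikes[i] for i in perm],
            bursting_spikes.t_start, bursting_spikes.t_end,
            active_mask=bursting_spikes.active_mask[perm])
        assert compute_synchrony(relabeled) == pytest.approx(chi, abs=1e-12)
        shifted = SpikeTrainSet(
            bursting_spikes.channels,
            [s + 5.0 for s in bursting_spikes.spikes],
            bursting_spikes.t_start + 5.0, bursting_spikes.t_end + 5.0,
            active_mask=bursting_spikes.active_mask)
        assert compute_synchrony(shifted) == pytest.approx(chi, abs=1e-9)

    def test_result_bounded_in_unit_interval(self, bursting_spikes, independent_spikes):
        for sts in (bursting_spikes, independent_spikes):
            assert 0.0 <= compute_synchrony(sts) <= 1.0 + 1e-12

    def test_silent_channels_raise(self):
        sts = _sts([[], []], t1=10.0)
        with pytest.raises(SilentRecordingError):
            compute_synchrony(sts)

    def test_squared_variant_is_square(self, bursting_spikes):
        chi = compute_synchrony(bursting_spikes)
        chi2 = compute_synchrony(bursting_spikes, squared=True)
        assert chi2 == pytest.approx(chi ** 2)


def _dft_snr_oracle(x: np.ndarray, fs: float, half: int = 2) -> tuple[float, float]:
    """Independent SNR bookkeeping on the raw periodogram."""
    x = x - x.mean()
    p = np.abs(np.fft.rfft(x)) ** 2
    p[0] = 0.0
    peak = int(np.argmax(p))
    df = fs / x.size
    f0 = peak * df
    band = slice(max(peak - half, 1), peak + half + 1)
    psig = p[band].sum()
    mask = np.ones(p.size, bool)
    mask[: half + 1] = False
    mask[band] = False
    for h in range(2, 8):
        hb = int(round(h * f0 / df))
        if hb < p.size:
            mask[max(hb - half, 0): hb + half + 1] = False
    pnoise = p[mask].mean() * p.size
    return 10 * np.log10(psig / pnoise), f0


class TestOscillationIntensity:
    @pytest.fixture
    def noisy_sine(self):
        rng = np.random.default_rng(11)
        fs, dur = 100.0, 300.0
        t = np.arange(int(fs * dur)) / fs
        noise = rng.standard_normal(t.size)
        return t, fs, noise

    def test_matches_independent_dft_oracle(self, noisy_sine):
        t, fs, noise = noisy_sine
        x = 10 + 5 * np.sin(2 * np.pi * 1.0 * t) + 0.5 * noise
        fr = FiringRateSignal(np.clip(x, 0, None), dt=1 / fs, window=0.1)
        snr, f0 = compute_oscillation_intensity(fr)
        o_snr, o_f0 = _dft_snr_oracle(np.clip(x, 0, None), fs)
        assert f0 == pytest.approx(1.0, abs=0.05)
        assert o_f0 == pytest.approx(1.0, abs=0.01)
        assert snr == pytest.approx(o_snr, abs=1.0)

    def test_amplitude_doubling_adds_six_db(self, noisy_sine):
        t, fs, noise = noisy_sine
        snrs = []
        for amp in (5.0, 10.0):
            x = 20 + amp * np.sin(2 * np.pi * 1.0 * t) + 0.5 * noise
            fr = FiringRateSignal(np.clip(x, 0, None), dt=1 / fs, window=0.1)
            snrs.append(compute_oscillation_intensity(fr)[0])
        assert snrs[1] - snrs[0] == pytest.approx(20 * np.log10(2), abs=0.5)

    def test_mean_shift_invariance(self, noisy_sine):
        t, fs, noise = noisy_sine
        x = 10 + 5 * np.sin(2 * np.pi * 1.0 * t) + 0.5 * noise
        a = compute_oscillation_intensity(FiringRateSignal(x + 5, dt=1 / fs, window=0.1))
        b = compute_oscillation_intensity(FiringRateSignal(x + 30, dt=1 / fs, window=0.1))
        assert a[0] == pytest.approx(b[0], abs=1e-9)

    def test_monotone_in_sinusoid_amplitude(self, noisy_sine):
        t, fs, noise = noisy_sine
        snrs = []
        for amp in (1.0, 2.0, 4.0, 8.0):
            x = 20 + amp * np.sin(2 * np.pi * 1.0 * t) + 0.5 * noise
            snrs.append(compute_oscillation_intensity(
                FiringRateSignal(np.clip(x, 0, None), dt=1 / fs, window=0.1))[0])
        assert snrs == sorted(snrs)

    def test_white_noise_far_below_periodic_signal(self, noisy_sine):
        t, fs, noise = noisy_sine
        snr_noise, _ = compute_oscillation_intensity(
            FiringRateSignal(10 + noise, dt=1 / fs, window=0.1))
        x = 10 + 5 * np.sin(2 * np.pi * 1.0 * t) + 0.5 * noise
        snr_sig, _ = compute_oscillation_intensity(
            FiringRateSignal(np.clip(x, 0, None), dt=1 / fs, window=0.1))
        assert snr_noise < 3.0
        assert snr_noise < snr_sig - 10

    def test_flat_signal_returns_sentinel(self):
        fr = FiringRateSignal(np.full(4000, 3.0), dt=0.01, window=0.1)
        snr, f0 = compute_oscillation_intensity(fr)
        assert np.isnan(snr) and np.isnan(f0)

    def test_short_signal_rejected(self):
        fr = FiringRateSignal(np.ones(20), dt=0.01, window=0.1)
        with pytest.raises(ValueError):
            compute_oscillation_intensity(fr)


class TestAverageFiringRate:
    def test_single_channel(self):
        sts = _sts([np.linspace(0.5, 9.5, 10)], t1=10.0)
        assert average_firing_rate(sts) == pytest.approx(1.0)

    def test_normalised_per_active_electrode(self):
        sts = SpikeTrainSet([0, 1], [np.linspace(0.5, 9.5, 10), np.array([5.0])],
                            0.0, 10.0, active_mask=np.array([True, True]))
        assert average_firing_rate(sts) == pytest.approx(11 / 20)

    def test_empty_recording_is_zero(self):
        assert average_firing_rate(_sts([[]], t1=10.0)) == 0.0


class TestWaveletSpectrogram:
    def test_sinusoid_ridge_at_fundamental(self):
        fs = 20.0
        t = np.arange(int(fs * 120)) / fs
        fr = FiringRateSignal(10 + 5 * np.sin(2 * np.pi * 0.5 * t), dt=1 / fs, window=0.1)
        spec = compute_wavelet_spectrogram(fr, freq_range=(0.1, 2.0))
        ridge = spec.ridge()[200:-200]  # away from cone-of-influence edges
        step = np.diff(np.log(spec.frequencies)).max()
        assert np.all(np.abs(np.log(ridge) - np.log(0.5)) <= 1.5 * step)

    def test_chirp_ridge_increases(self):
        fs = 20.0
        dur = 200.0
        t = np.arange(int(fs * dur)) / fs
        from scipy.signal import chirp
        fr = FiringRateSignal(10 + 5 * chirp(t, 0.2, dur, 2.0), dt=1 / fs, window=0.1)
        spec = compute_wavelet_spectrogram(fr, freq_range=(0.1, 3.0))
        ridge = spec.ridge()[300:-300]
        thirds = np.array_split(ridge, 3)
        medians = [np.median(x) for x in thirds]
        assert medians[0] < medians[1] < medians[2]

    def test_constant_signal_has_no_ridge_energy(self):
        fr = FiringRateSignal(np.full(2000, 5.0), dt=0.05, window=0.1)
        spec = compute_wavelet_spectrogram(fr, freq_range=(0.1, 2.0))
        assert np.max(spec.magnitude) == pytest.approx(0.0, abs=1e-9)

    def test_invalid_range_rejected(self):
        fr = FiringRateSignal(np.ones(100), dt=0.05, window=0.1)
        with pytest.raises(ValueError):
            compute_wavelet_spectrogram(fr, freq_range=(0.0, 100.0))


class TestSlidingWindowMetrics:
    def test_full_window_equals_whole_recording(self, bursting_spikes):
        from adfc import compute_synchrony
        df = sliding_window_metrics(bursting_spikes, window=bursting_spikes.duration,
                                    step=bursting_spikes.duration)
        assert len(df) == 1
        assert df["firing_rate"].iloc[0] == pytest.approx(
            average_firing_rate(bursting_spikes))
        assert df["synchrony"].iloc[0] == pytest.approx(
            compute_synchrony(bursting_spikes))

    def test_stationary_recording_fluctuates_around_global(self, bursting_spikes):
        df = sliding_window_metrics(bursting_spikes, window=10.0)
        assert df["synchrony"].mean() == pytest.approx(
            compute_synchrony(bursting_spikes), rel=0.15)
        assert df["firing_rate"].mean() == pytest.approx(
            average_firing_rate(bursting_spikes), rel=0.15)

    def test_synchronous_half_scores_higher(self, bursting_spikes, independent_spikes):
        sync = bursting_spikes
        rng = np.random.default_rng(3)
        async_trains = [np.sort(60.0 + rng.uniform(0, 60, 150))
                        for _ in range(sync.n_channels)]
        trains = [np.concatenate([a, b]) for a, b in zip(sync.spikes, async_trains)]
        sts = SpikeTrainSet(sync.channels, trains, 0.0, 120.0,
                            active_mask=np.ones(sync.n_channels, dtype=bool))
        df = sliding_window_metrics(sts, window=10.0)
        first = df[df["t"] < 55]["synchrony"].mean()
        second = df[df["t"] > 65]["synchrony"].mean()
        assert first > second + 0.2

    def test_degenerate_window_rejected(self, bursting_spikes):
        with pytest.raises(ValueError):
            sliding_window_metrics(bursting_spikes, window=0.0)
        with pytest.raises(ValueError):
            sliding_window_metrics(bursting_spikes, window=1e4)
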