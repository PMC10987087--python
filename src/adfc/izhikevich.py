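"""Izhikevich-network testbed for closed-loop control experiments.

Randomly weighted all-to-all networks of Izhikevich neurons with a
tunable excitatory fraction and overall synaptic scale, following the
classic reference network: regular-spiking (RS) excitatory neurons
(a=0.02, b=0.2, c=-65, d=8), fast-spiking (FS) inhibitory neurons
(a=0.1, b=0.2, c=-65, d=2), excitatory weights uniform on [0, 0.5] and
inhibitory on [-1, 0], per-step Gaussian "thalamic" noise (SD 5 for RS,
2 for FS) and 1 ms steps with two 0.5 ms half-updates of v.

A closed-loop run simulates a stabilisation segment, a spontaneous OFF
segment and an ON segment in which an aDFC controller consumes the
population firing rate computed online from the simulated spikes and
injects instantaneous current pulses into a randomly chosen pool of
neurons. Sweeping (excitatory fraction x weight scale) maps where the
network is controllable: synchrony rises along both axes, and in the
intermediate regime aDFC can desynchronise the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .controllers import ControllerConfig, StreamingController
from .metrics import average_firing_rate, compute_synchrony, detect_network_bursts
from .types import FiringRateSignal, SpikeTrainSet, StimulationSchedule

__all__ = [
    "IzhNetworkConfig",
    "IzhNetworkState",
    "SimulationResult",
    "build_network",
    "step_network",
    "apply_stimulus",
    "run_closed_loop",
    "sweep_parameter_grid",
    "default_sim_controller_config",
]

# Izhikevich parameter sets
RS_PARAMS = (0.02, 0.2, -65.0, 8.0)  # regular-spiking excitatory
FS_PARAMS = (0.1, 0.2, -65.0, 2.0)   # fast-spiking inhibitory

#: χ box width for in silico synchrony (s). Network-burst periods in the
#: model are roughly ten times faster than in vitro, so the 50 ms in vitro
#: box is rescaled accordingly.
SIM_BOX_WIDTH = 0.005
#: FR window for the in silico controller (s); the in vitro 0.1 s window
#: rescaled to the faster burst timescale.
SIM_FR_WINDOW = 0.010

#: Scaled-down controllability-map defaults: a 3x3 grid spanning the
#: sparse/chaotic, intermediate (controllable) and strongly bursting
#: regimes at N = 300 neurons.
SWEEP_FRAC_EXC = (0.6, 0.8, 0.9)
SWEEP_WEIGHT_SCALE = (0.6, 1.0, 2.0)
SWEEP_N_NEURONS = 300


@dataclass
class IzhNetworkConfig:
    """Network architecture and drive parameters.

    ``weight_scale`` multiplies the base random weight matrix; 1.0
    corresponds to the reference network's weights at ``n_neurons=1000``
    (weights are normalised by 1000/N so total synaptic input is
    comparable across network sizes).
    """

    n_neurons: int = 1000
    frac_exc: float = 0.8
    weight_scale: float = 1.0
    n_stim: int = 100
    stim_amplitude: float = 20.0
    noise_exc: float = 5.0
    noise_inh: float = 2.0
    dt: float = 1.0  # ms
    seed: int = 0
    self_connections: bool = False
    normalize_by_size: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_exc <= 1.0):
            raise ValueError("frac_exc must be in [0, 1]")
        if self.n_stim > self.n_neurons:
            raise ValueError("n_stim cannot exceed n_neurons")
        if self.dt <= 0 or self.dt > 1.0:
            raise ValueError("dt must be in (0, 1] ms")
        if self.weight_scale < 0:
            raise ValueError("weight_scale must be nonnegative")


@dataclass
class IzhNetworkState:
    """Full mutable state of a simulated network (times in ms)."""

    v: np.ndarray
    u: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    S: np.ndarray          # signed weights, row = postsynaptic
    exc_mask: np.ndarray
    stim_set: np.ndarray   # indices of the stimulated pool
    t: float = 0.0
    config: IzhNetworkConfig | None = None


def build_network(config: IzhNetworkConfig, rng: np.random.Generator | None = None) -> IzhNetworkState:
    """Construct a random all-to-all network per the reference recipe."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_neurons
    n_exc = int(np.floor(config.frac_exc * n))
    exc_mask = np.zeros(n, dtype=bool)
    exc_mask[:n_exc] = True
    a = np.where(exc_mask, RS_PARAMS[0], FS_PARAMS[0])
    b = np.where(exc_mask, RS_PARAMS[1], FS_PARAMS[1])
    c = np.where(exc_mask, RS_PARAMS[2], FS_PARAMS[2])
    d = np.where(exc_mask, RS_PARAMS[3], FS_PARAMS[3])
    S = np.empty((n, n))
    S[:, exc_mask] = 0.5 * rng.random((n, n_exc))
    S[:, ~exc_mask] = -rng.random((n, n - n_exc))
    scale = config.weight_scale * (1000.0 / n if config.normalize_by_size else 1.0)
    S *= scale
    if not config.self_connections:
        np.fill_diagonal(S, 0.0)
    v = np.full(n, -65.0)
    u = b * v
    stim_set = rng.choice(n, size=config.n_stim, replace=False)
    return IzhNetworkState(v=v, u=u, a=a, b=b, c=c, d=d, S=S, exc_mask=exc_mask,
                           stim_set=stim_set, t=0.0, config=config)


def step_network(
    state: IzhNetworkState,
    external_current: np.ndarray | float = 0.0,
    rng: np.random.Generator | None = None,
    dt: float | None = None,
) -> np.ndarray:
    """Advance the network one time step in place; return fired indices.

    Neurons at v >= 30 mV at step entry spike and reset (v <- c,
    u <- u + d); the input current is the Gaussian noise drive plus the
    summed weights of the neurons that fired this step plus
    ``external_current``; v advances with two half-steps of the quadratic
    Izhikevich update and u with u' = a(bv - u).
    """
    cfg = state.config
    dt = cfg.dt if dt is None else dt
    fired = np.flatnonzero(state.v >= 30.0)
    state.v[fired] = state.c[fired]
    state.u[fired] += state.d[fired]
    if rng is not None:
        noise = np.where(state.exc_mask, cfg.noise_exc, cfg.noise_inh) * rng.standard_normal(state.v.size)
    else:
        noise = 0.0
    current = noise + np.asarray(external_current, dtype=float)
    if fired.size:
        current = current + state.S[:, fired].sum(axis=1)
    v, u = state.v, state.u
    with np.errstate(invalid="ignore", over="ignore"):
        for _ in range(2):
            v += (dt / 2.0) * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
        u += dt * state.a * (state.b * v - u)
    if not np.all(np.isfinite(v)):
        raise FloatingPointError(f"non-finite membrane potential at t={state.t} ms")
    state.t += dt
    return fired


def apply_stimulus(state: IzhNetworkState, amplitude: float | None = None) -> np.ndarray:
    """Current vector delivering one instantaneous pulse to the stim pool.

    ``amplitude`` model-current units (defaults to the configured 20) on
    the stimulated neurons for exactly one step, zero elsewhere.
    """
    amp = state.config.stim_amplitude if amplitude is None else amplitude
    current = np.zeros(state.v.size)
    current[state.stim_set] = amp
    return current


@dataclass
class SimulationResult:
    """Outcome of a closed-loop run (spike times converted to seconds)."""

    spikes: SpikeTrainSet
    schedule: StimulationSchedule
    segments: dict  # {"stabilise": (t0, t1), "off": ..., "on": ...} in s
    config: IzhNetworkConfig
    controller_config: ControllerConfig | None
    fr_trace: FiringRateSignal | None = None

    def segment_spikes(self, name: str) -> SpikeTrainSet:
        t0, t1 = self.segments[name]
        return self.spikes.slice(t0, t1)


def default_sim_controller_config(**overrides) -> ControllerConfig:
    """aDFC settings rescaled to the model's ~10x faster burst timescale.

    In vitro bounds (1 < SF < 20 Hz), window (0.1 s) and typical initial
    period (~1 s) map to 10 < SF < 200 Hz, 10 ms and ~0.1 s. The burst
    threshold is recalibrated per simulation from the OFF segment.
    """
    defaults = dict(
        gain=5.0, period=0.1, adaptive=True, sf_min=10.0, sf_max=200.0,
        burst_threshold=50.0, burst_min_interval=0.01, fr_window=SIM_FR_WINDOW,
        positive_only=True,
    )
    defaults.update(overrides)
    return ControllerConfig(**defaults)


class _OnlineFR:
    """Trailing-window population rate computed as the simulation runs."""

    def __init__(self, n_neurons: int, window_s: float, dt_s: float) -> None:
        self.n = n_neurons
        self.window_steps = max(1, int(round(window_s / dt_s)))
        self.window_s = self.window_steps * dt_s
        self.counts = np.zeros(self.window_steps, dtype=np.int64)
        self.head = 0
        self.total = 0

    def push(self, n_fired: int) -> float:
        self.total += n_fired - self.counts[self.head]
        self.counts[self.head] = n_fired
        self.head = (self.head + 1) % self.window_steps
        return self.total / (self.n * self.window_s)


def run_closed_loop(
    network_config: IzhNetworkConfig,
    controller_config: ControllerConfig | None = None,
    t_stabilise: float = 500.0,
    t_off: float = 2000.0,
    t_on: float = 2000.0,
    seed_controller: int = 0,
    calibrate_threshold: bool = True,
    gain: float | None = None,
) -> SimulationResult:
    """Stabilise + OFF + ON closed-loop simulation (durations in ms).

    During ON the controller consumes the online population firing rate
    (all neurons as "electrodes", trailing window) and a stimulus injects
    one instantaneous current pulse into the stimulated pool. With
    ``calibrate_threshold`` the burst-detection threshold and the initial
    period are set from the OFF segment: the threshold midway between the
    median and peak OFF firing rate, the period as the median OFF
    inter-burst interval (the in vitro procedure tuned both during
    pre-experiment monitoring). ``gain=0`` yields a null intervention.
    """
    if controller_config is None:
        controller_config = default_sim_controller_config()
    if gain is not None:
        # gain == 0 disables stimulation entirely (null control)
        from dataclasses import replace as _rep
        controller_config = _rep(controller_config, gain=max(gain, 1e-12))
        null_gain = gain == 0
    else:
        null_gain = False
    rng = np.random.default_rng(network_config.seed)
    state = build_network(network_config, rng=rng)
    dt_ms = network_config.dt
    dt_s = dt_ms / 1000.0
    n_steps = {k: int(round(v / dt_ms)) for k, v in
               (("stab", t_stabilise), ("off", t_off), ("on", t_on))}
    spike_t: list[float] = []
    spike_i: list[np.ndarray] = []
    online_fr = _OnlineFR(network_config.n_neurons, SIM_FR_WINDOW, dt_s)
    fr_samples: list[float] = []

    def advance(n: int, controller: StreamingController | None = None):
        stim_times = []
        for _ in range(n):
            ext: np.ndarray | float = 0.0
            fr_now = online_fr.counts.sum() / (online_fr.n * online_fr.window_s)
            if controller is not None and controller.process_sample(fr_now):
                ext = apply_stimulus(state)
                stim_times.append(state.t / 1000.0)
            fired = step_network(state, ext, rng=rng)
            if fired.size:
                spike_t.append(state.t / 1000.0)
                spike_i.append(fired)
            online_fr.push(fired.size)
            fr_samples.append(fr_now)
        return stim_times

    advance(n_steps["stab"])
    t_off0 = state.t / 1000.0
    advance(n_steps["off"])
    t_on0 = state.t / 1000.0

    cc = controller_config
    if calibrate_threshold:
        off_fr = np.asarray(fr_samples[n_steps["stab"]:])
        baseline = float(np.median(off_fr))
        peak = float(np.max(off_fr)) if off_fr.size else 0.0
        if peak > baseline:
            from dataclasses import replace as _rep
            thr = baseline + 0.5 * (peak - baseline)
            cc = _rep(cc, burst_threshold=thr)
            fr_sig = FiringRateSignal(off_fr, dt=dt_s, window=SIM_FR_WINDOW, t0=t_off0)
            bursts = detect_network_bursts(fr_sig, threshold=thr,
                                           min_interval=cc.burst_min_interval)
            if bursts.n >= 3:
                cc = _rep(cc, period=float(np.median(bursts.intervals())))

    controller = StreamingController(cc, dt=dt_s, t0=state.t / 1000.0)
    rng_ctrl = np.random.default_rng(seed_controller)  # reserved for stochastic protocols
    del rng_ctrl
    if null_gain:
        advance(n_steps["on"])
        stim_times = []
    else:
        stim_times = advance(n_steps["on"], controller)
    t_end = state.t / 1000.0

    # neuron-indexed spike trains in seconds
    n = network_config.n_neurons
    trains: list[list[float]] = [[] for _ in range(n)]
    for t, idx in zip(spike_t, spike_i):
        for i in idx:
            trains[i].append(t)
    sts = SpikeTrainSet(
        list(range(n)), [np.asarray(tr) for tr in trains], 0.0, t_end,
        active_mask=np.ones(n, dtype=bool),
    )
    schedule = StimulationSchedule(np.asarray(stim_times),
                                   amplitude=network_config.stim_amplitude,
                                   protocol="aDFC" if cc.adaptive else "DFC")
    fr_trace = FiringRateSignal(np.asarray(fr_samples), dt=dt_s,
                                window=online_fr.window_s, t0=0.0)
    return SimulationResult(
        spikes=sts, schedule=schedule,
        segments={"stabilise": (0.0, t_off0), "off": (t_off0, t_on0), "on": (t_on0, t_end)},
        config=network_config, controller_config=cc, fr_trace=fr_trace,
    )


def _segment_metrics(result: SimulationResult, name: str) -> tuple[float, float]:
    seg = result.segment_spikes(name)
    try:
        chi = compute_synchrony(seg, box_width=SIM_BOX_WIDTH)
    except ValueError:
        chi = float("nan")
    return chi, average_firing_rate(seg)


def sweep_parameter_grid(
    frac_exc_grid,
    weight_scale_grid,
    n_reps: int = 5,
    n_neurons: int = 1000,
    seed: int = 0,
    controller_config: ControllerConfig | None = None,
    **closed_loop_kwargs,
) -> pd.DataFrame:
    """Controllability map over (excitatory fraction x synaptic scale).

    Each cell runs ``n_reps`` independent closed-loop simulations and
    reports mean OFF synchrony/firing rate and the mean ON-OFF change in
    both. Deterministic given ``seed``.
    """
    rows = []
    master = np.random.SeedSequence(seed)
    grids = [(fe, ws) for fe in frac_exc_grid for ws in weight_scale_grid]
    seeds = master.generate_state(len(grids) * n_reps) % (2 ** 31)
    k = 0
    for fe, ws in grids:
        cell = {"frac_exc": fe, "weight_scale": ws}
        chi_off, fr_off, dchi, dfr = [], [], [], []
        for _ in range(n_reps):
            cfg = IzhNetworkConfig(n_neurons=n_neurons, frac_exc=fe, weight_scale=ws,
                                   n_stim=max(1, n_neurons // 10), seed=int(seeds[k]))
            k += 1
            res = run_closed_loop(cfg, controller_config, **closed_loop_kwargs)
            co, fo = _segment_metrics(res, "off")
            cn, fn = _segment_metrics(res, "on")
            chi_off.append(co)
            fr_off.append(fo)
            dchi.append(cn - co)
            dfr.append(fn - fo)
        cell.update(
            synchrony_off=float(np.nanmean(chi_off)),
            firing_rate_off=float(np.nanmean(fr_off)),
            d_synchrony=float(np.nanmean(dchi)),
            d_firing_rate=float(np.nanmean(dfr)),
            d_synchrony_median=float(np.nanmedian(dchi)),
        )
        rows.append(cell)
    return pd.DataFrame(rows)
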