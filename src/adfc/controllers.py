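"""Delayed feedback control of population oscillations.

The controller filters the instantaneous population firing rate FR(t)
with a damped oscillator

    x'' + ω x' + ω² x = k FR(t),          k = ω,

takes ẋ as its output, and builds the actuation (stimulation-frequency)
signal by subtracting the ongoing oscillation from its half-period
delayed copy,

    SF(t) = K ( ẋ(t − T/2) − ẋ(t) ).

A stimulus fires when t > t_last + 1/SF(t), bounded so stimulation only
occurs for sf_min < SF < sf_max (1 and 20 Hz in the MEA experiments).
For an oscillatory FR this places stimuli at the antiphase of the
ongoing oscillation. The adaptive variant (aDFC) detects synchronous
events (network bursts) online and re-estimates the oscillation period
T — hence the delay T/2 and the filter frequency ω = 2π/T — as the
median of the recent inter-burst intervals. Canonical DFC keeps T and ω
fixed at their initial values. A Poisson generator provides the
open-loop random-stimulation control protocol.

The oscillator is advanced with the exact zero-order-hold discretisation
of the linear ODE (closed-form 2x2 matrix exponential), which is
unconditionally stable and exact for the sampled, piecewise-constant FR
input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import FiringRateSignal, StimulationSchedule

__all__ = [
    "OscillatorState",
    "ControllerConfig",
    "ControllerTrace",
    "oscillator_step",
    "compute_actuation",
    "should_stimulate",
    "update_period_estimate",
    "run_controller",
    "generate_poisson_schedule",
]


# ---------------------------------------------------------------------------
# Damped-oscillator filter
# ---------------------------------------------------------------------------

def _zoh_propagator(omega: float, dt: float) -> tuple[np.ndarray, float]:
    """Exact one-step propagator of x'' + ω x' + ω² x = u (u held constant).

    Returns (Phi, gain) with state s = [x, ẋ]:
        s' = Phi @ (s - s_ss) + s_ss,   s_ss = [u/ω², 0].
    The system is underdamped with decay ω/2 and ringing ω·sqrt(3)/2.
    """
    alpha = omega / 2.0
    wd = omega * np.sqrt(3.0) / 2.0
    e = np.exp(-alpha * dt)
    c, s = np.cos(wd * dt), np.sin(wd * dt)
    phi = e * np.array([
        [c + (alpha / wd) * s, s / wd],
        [-(omega ** 2 / wd) * s, c - (alpha / wd) * s],
    ])
    return phi, 1.0 / omega ** 2


@dataclass
class OscillatorState:
    """State of the damped-oscillator firing-rate filter.

    ``xdot`` is the controller's output signal. ``k`` defaults to ω so the
    oscillator amplitude does not scale with the network's periodicity
    (unit gain and zero phase at resonance).
    """

    x: float = 0.0
    xdot: float = 0.0
    omega: float = 2.0 * np.pi
    k: float | None = None

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.k is None:
            self.k = self.omega


def oscillator_step(state: OscillatorState, fr_sample: float, dt: float) -> OscillatorState:
    """Advance the filter one sample with FR held constant over the step."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    phi, inv_w2 = _zoh_propagator(state.omega, dt)
    x_ss = state.k * fr_sample * inv_w2
    dx, dxd = state.x - x_ss, state.xdot
    x_new = phi[0, 0] * dx + phi[0, 1] * dxd + x_ss
    xd_new = phi[1, 0] * dx + phi[1, 1] * dxd
    return replace(state, x=x_new, xdot=xd_new)


# ---------------------------------------------------------------------------
# Actuation and stimulus triggering
# ---------------------------------------------------------------------------

def compute_actuation(xdot_now: float, xdot_delayed: float, gain: float) -> float:
    """Stimulation frequency SF = K (ẋ(t − T/2) − ẋ(t)), in Hz."""
    return gain * (xdot_delayed - xdot_now)


@dataclass
class ControllerConfig:
    """Parameters of a DFC/aDFC run.

    ``gain`` is K in stimuli/s per unit ẋ difference; ``period`` the
    initial oscillation period T (s), supplied by the operator from
    pre-experiment monitoring; ``adaptive`` selects aDFC. ``sf_min`` and
    ``sf_max`` bound the stimulation frequency (stimuli only fire while
    sf_min < SF; SF is clipped at sf_max, which also enforces a
    refractory interval of 1/sf_max). ``positive_only`` zeroes negative
    actuation (excitatory-only stimulation, used in silico).
    """

    gain: float = 2.0
    period: float = 1.0
    adaptive: bool = True
    sf_min: float = 1.0
    sf_max: float = 20.0
    burst_threshold: float = 10.0
    burst_min_interval: float = 0.1
    fr_window: float = 0.1
    positive_only: bool = False
    n_intervals: int = 3  # inter-burst intervals pooled in the T estimate
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.sf_min < self.sf_max):
            raise ValueError("need 0 < sf_min < sf_max")
        if self.period <= 0 or self.gain <= 0:
            raise ValueError("period and gain must be positive")
        if self.burst_threshold <= 0 or self.burst_min_interval < 0:
            raise ValueError("invalid burst-detection parameters")


def should_stimulate(t: float, t_last_stim: float, sf: float, config: ControllerConfig) -> bool:
    """Decide whether to fire a stimulus at time ``t``.

    True iff the (clipped) stimulation frequency exceeds ``sf_min`` and
    the time since the last stimulus exceeds ``1/SF``. Clipping SF at
    ``sf_max`` guarantees inter-stimulus intervals above ``1/sf_max``.
    """
    if t < t_last_stim:
        raise ValueError("t must not precede t_last_stim")
    sf_eff = min(sf, config.sf_max)
    return sf_eff > config.sf_min and (t - t_last_stim) > 1.0 / sf_eff


def update_period_estimate(
    burst_times: np.ndarray, current_T: float, config: ControllerConfig
) -> tuple[float, float]:
    """Re-estimate (T, ω) from recent synchronous events.

    With at least two bursts, T is the median of the last ``n_intervals``
    inter-burst intervals and ω = 2π/T; otherwise the current values are
    returned unchanged.
    """
    burst_times = np.asarray(burst_times, dtype=float)
    if burst_times.size < 2:
        return current_T, 2.0 * np.pi / current_T
    intervals = np.diff(burst_times)[-config.n_intervals:]
    T = float(np.median(intervals))
    return T, 2.0 * np.pi / T


# ---------------------------------------------------------------------------
# Streaming controller
# ---------------------------------------------------------------------------

@dataclass
class ControllerTrace:
    """Per-sample internals of a controller run (shared time grid)."""

    t: np.ndarray
    xdot: np.ndarray
    xdot_delayed: np.ndarray
    sf: np.ndarray
    T_history: np.ndarray
    omega_history: np.ndarray
    burst_times: np.ndarray


class _DelayBuffer:
    """Growable history of ẋ samples with linear interpolation at t − T/2."""

    def __init__(self, dt: float, capacity: int = 1024) -> None:
        self.dt = dt
        self.data = np.zeros(capacity)
        self.n = 0

    def push(self, value: float) -> None:
        if self.n == self.data.size:
            self.data = np.concatenate([self.data, np.zeros(self.data.size)])
        self.data[self.n] = value
        self.n += 1

    def read_delayed(self, delay: float) -> float:
        """ẋ at (current sample time − delay); zero before the start."""
        idx = (self.n - 1) - delay / self.dt
        if idx < 0:
            return 0.0
        i = int(np.floor(idx))
        frac = idx - i
        if i + 1 >= self.n:
            return float(self.data[self.n - 1])
        return float((1 - frac) * self.data[i] + frac * self.data[i + 1])


class StreamingController:
    """Online DFC/aDFC: consume FR samples one at a time, emit stimuli.

    Strictly causal — each decision uses only samples seen so far. Usable
    both on a pre-recorded :class:`FiringRateSignal` (via
    :func:`run_controller`) and inside a closed-loop simulation that
    feeds samples as they are generated.
    """

    def __init__(self, config: ControllerConfig, dt: float, t0: float = 0.0) -> None:
        self.config = config
        self.dt = dt
        self.t = t0
        omega = 2.0 * np.pi / config.period
        self.state = OscillatorState(omega=omega)
        self.T = config.period
        self.buffer = _DelayBuffer(dt)
        self.t_last_stim = -np.inf
        self.prev_fr: float | None = None
        self.burst_times: list[float] = []
        self.stim_times: list[float] = []
        self.trace: dict[str, list[float]] = {
            "t": [], "xdot": [], "xdot_delayed": [], "sf": [],
            "T": [], "omega": [],
        }

    def _detect_burst(self, fr_sample: float) -> bool:
        cfg = self.config
        prev = self.prev_fr if self.prev_fr is not None else 0.0
        if fr_sample >= cfg.burst_threshold and prev < cfg.burst_threshold:
            if not self.burst_times or self.t - self.burst_times[-1] >= cfg.burst_min_interval:
                return True
        return False

    def process_sample(self, fr_sample: float) -> bool:
        """Advance one FR sample; return True if a stimulus fires now."""
        cfg = self.config
        if self._detect_burst(fr_sample):
            self.burst_times.append(self.t)
            if cfg.adaptive:
                self.T, omega = update_period_estimate(
                    np.asarray(self.burst_times), self.T, cfg)
                self.state = replace(self.state, omega=omega, k=omega)
        self.prev_fr = fr_sample
        self.state = oscillator_step(self.state, fr_sample, self.dt)
        self.buffer.push(self.state.xdot)
        delayed = self.buffer.read_delayed(self.T / 2.0)
        sf = compute_actuation(self.state.xdot, delayed, cfg.gain)
        if cfg.positive_only and sf < 0:
            sf = 0.0
        fire = should_stimulate(self.t, self.t_last_stim, sf, cfg)
        if fire:
            self.t_last_stim = self.t
            self.stim_times.append(self.t)
        tr = self.trace
        tr["t"].append(self.t)
        tr["xdot"].append(self.state.xdot)
        tr["xdot_delayed"].append(delayed)
        tr["sf"].append(sf)
        tr["T"].append(self.T)
        tr["omega"].append(self.state.omega)
        self.t += self.dt
        return fire

    def finalize(self, protocol: str | None = None,
                 amplitude: float | None = None) -> tuple[StimulationSchedule, ControllerTrace]:
        label = protocol or ("aDFC" if self.config.adaptive else "DFC")
        schedule = StimulationSchedule(
            times=np.asarray(self.stim_times),
            amplitude=amplitude if amplitude is not None else self.config.amplitude,
            protocol=label,
        )
        tr = self.trace
        trace = ControllerTrace(
            t=np.asarray(tr["t"]), xdot=np.asarray(tr["xdot"]),
            xdot_delayed=np.asarray(tr["xdot_delayed"]), sf=np.asarray(tr["sf"]),
            T_history=np.asarray(tr["T"]), omega_history=np.asarray(tr["omega"]),
            burst_times=np.asarray(self.burst_times),
        )
        return schedule, trace


def run_controller(
    fr_stream: FiringRateSignal, config: ControllerConfig
) -> tuple[StimulationSchedule, ControllerTrace]:
    """Run DFC (``adaptive=False``) or aDFC over a recorded FR stream.

    Streams through the samples once with no lookahead; bursts are
    detected online with the same threshold-crossing rule as
    :func:`adfc.metrics.detect_network_bursts`, and under aDFC each burst
    re-tunes (T, ω).
    """
    ctrl = StreamingController(config, dt=fr_stream.dt, t0=fr_stream.t0)
    for sample in fr_stream.values:
        ctrl.process_sample(float(sample))
    return ctrl.finalize()


# ---------------------------------------------------------------------------
# Poisson (random stimulation) protocol
# ---------------------------------------------------------------------------

def generate_poisson_schedule(
    rate: float, duration: float, seed: int | np.random.Generator = 0,
    amplitude: float = 1.0,
) -> StimulationSchedule:
    """Homogeneous Poisson stimulus train on [0, duration).

    Used as the open-loop random-stimulation control, with ``rate`` set to
    the mean stimulation frequency of a preceding aDFC trial.
    """
    if rate < 0:
        raise ValueError("rate cannot be negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if rate == 0 or duration <= 0:
        return StimulationSchedule(np.array([]), amplitude, protocol="Poisson")
    n = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, size=n))
    # strict monotonicity: drop exact duplicates (measure-zero event)
    times = np.unique(times)
    return StimulationSchedule(times, amplitude, protocol="Poisson")
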