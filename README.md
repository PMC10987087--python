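# adfc — adaptive delayed feedback control for neuronal desynchronisation

Pathological brain states such as Parkinsonian tremor and epileptic
seizures involve excessive synchronous oscillations of neuronal
populations. Delayed feedback control (DFC) is a closed-loop
stimulation strategy that counteracts an oscillation by actuating
proportionally to the difference between the ongoing activity and its
half-period-delayed copy, so stimulation lands at the antiphase of the
population rhythm and ceases once the rhythm is gone. Its adaptive
variant (**aDFC**) additionally detects synchronous events (network
bursts) online and re-tunes the delay and filter frequency as the
oscillation period changes — without this adaptation, fixed-delay DFC
can entrain the network to a new rhythm instead of suppressing it.

This package implements the full method as a tested Python library and
CLI for researchers in closed-loop neuromodulation:

* **Controllers** (`adfc.controllers`): the population firing rate
  FR(t) is filtered by a damped oscillator
  `ẍ + ωẋ + ω²x = k·FR(t)` with `k = ω`; the stimulation-frequency
  signal is `SF(t) = K(ẋ(t−T/2) − ẋ(t))`; a stimulus fires when
  `t > t_last + 1/SF(t)` with `sf_min < SF < sf_max`. aDFC re-estimates
  T (and ω = 2π/T) from the median of recent inter-burst intervals. A
  homogeneous Poisson generator provides the open-loop random
  stimulation control.
* **Metrics** (`adfc.metrics`): instantaneous firing rate (causal
  square window, spikes per active electrode per second), network-burst
  detection, the χ variance-ratio synchrony
  `χ² = Var(⟨Vᵢ⟩) / ⟨Var(Vᵢ)⟩` on binarised 50 ms occupancy signals,
  oscillation intensity as the SNR (dB) of the fundamental peak of the
  Welch PSD of FR, wavelet spectrograms, and sliding-window metric
  traces.
* **In silico testbed** (`adfc.izhikevich`): all-to-all random networks
  of Izhikevich neurons (regular-spiking excitatory, fast-spiking
  inhibitory) with tunable excitatory fraction and synaptic scale,
  closed-loop stimulable, plus a controllability sweep over the
  (E/I balance × weight scale) plane.
* **Experiment analysis** (`adfc.experiments`): OFF-ON-OFF trial
  metrics, fold-change normalisation, MANOVA (Wilks' lambda)
  controllability classification, PC1 projection of baseline dynamics,
  GMM/BIC state clustering, and time spent in the asynchronous state
  (synchrony < 0.5 and below-average firing rate).
* **Synthetic data** (`adfc.synthetic`): generators for quasiperiodic
  network bursting, multi-stable and drifting-period recordings, so
  everything is exercisable without recorded data.

## Worked example

Generate a minute of synthetic bursting culture activity (16
electrodes, ~1 s burst period), run aDFC over it, and measure the
effect surrogate quantities:

```python
import numpy as np
from adfc import (BurstingModel, ControllerConfig, generate_bursting,
                  compute_instantaneous_firing_rate, compute_metrics,
                  detect_network_bursts, run_controller)

spikes = generate_bursting(BurstingModel(n_channels=16, period=1.0,
                                         period_jitter=0.02, duration=60.0,
                                         seed=42))
print(compute_metrics(spikes))
# MetricsTriplet(synchrony=0.853, firing_rate=8.16,
#                oscillation_intensity=10.99, oscillation_frequency=0.933)

fr = compute_instantaneous_firing_rate(spikes)           # 0.1 s window
sched, trace = run_controller(fr, ControllerConfig(gain=1.0, period=0.8,
                                                   adaptive=True))
print(trace.T_history[-1], sched.n)
# 1.02 411
```

The metric triplet says the culture is highly synchronous (χ = 0.85 on
a 0–1 scale), fires ~8 spikes/electrode/s, and has a strong ~0.93 Hz
rhythm (11.0 dB above the noise floor). Starting from a deliberately
wrong initial period of 0.8 s, the adaptive controller converges to the
true ~1 s period (estimate 1.02 s) and delivers 411 stimuli
concentrated in the antiphase half-cycle of the ongoing oscillation.

The same pipeline is available from the shell:

```bash
adfc synth --seed 42 --out spikes.csv
adfc metrics --input spikes.csv --out metrics.json
adfc control --input spikes.csv --protocol adfc --gain 1 --period 0.8 --out run/
adfc simulate --seed 1 --out sim/          # closed-loop Izhikevich network
adfc sweep --reps 5 --seed 1 --out map.csv # controllability map
```

Every command writes a `manifest.json` with all parameters, seeds and
output hashes.

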