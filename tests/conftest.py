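import numpy as np
import pytest

from adfc import BurstingModel, SpikeTrainSet, generate_bursting


@pytest.fixture
def bursting_spikes() -> SpikeTrainSet:
    """60 s of quasiperiodic network bursting (T = 1 s, 2% jitter)."""
    model = BurstingModel(n_channels=16, period=1.0, period_jitter=0.02,
                          duration=60.0, seed=42)
    return generate_bursting(model)


@pytest.fixture
def independent_spikes() -> SpikeTrainSet:
    """16 independent Poisson trains (asynchronous activity)."""
    rng = np.random.default_rng(7)
    trains = [np.sort(rng.uniform(0, 100, rng.poisson(300))) for _ in range(16)]
    return SpikeTrainSet(list(range(16)), trains, 0.0, 100.0,
                         active_mask=np.ones(16, dtype=bool))
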