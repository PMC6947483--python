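import numpy as np
import pytest

from lateralline.ephys import SpikeTrain, detect_spikes, filter_motor_trace
from lateralline.synthgen import (
    SimConfig,
    simulate_motor_recording,
    simulate_stimulus_protocol,
    simulate_synapse_traces,
)


@pytest.fixture(scope="session")
def small_sim():
    """A compact synthetic dataset (trace level) shared across tests:
    120 s, 3 posterior + 3 anterior synapses (2 anterior suppressed)."""
    cfg = SimConfig(
        duration=120.0,
        n_synapses_posterior=3,
        n_synapses_anterior=3,
        n_anterior_suppressed=2,
        seed=11,
    )
    raw, gt = simulate_motor_recording(cfg)
    epochs = simulate_stimulus_protocol(cfg)
    true_spikes = SpikeTrain(times=gt.spike_times, source_rate=cfg.ephys_rate)
    traces, gt2 = simulate_synapse_traces(cfg, true_spikes, epochs)
    gt.merge(gt2)
    spikes = detect_spikes(filter_motor_trace(raw))
    return dict(
        cfg=cfg, raw=raw, gt=gt, epochs=epochs,
        true_spikes=true_spikes, spikes=spikes, traces=traces,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
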