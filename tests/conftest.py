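import numpy as np
import pytest

from opmbursts.containers import RawRecording
from opmbursts.paradigm import generate_schedule
from opmbursts.synth import (
    BurstSpec,
    build_helmet_array,
    make_source_model,
    simulate_recording,
)


def make_recording(data: np.ndarray, fs: float, events=None) -> RawRecording:
    """Wrap a raw array in a RawRecording with dummy unit-z geometry."""
    data = np.atleast_2d(np.asarray(data, float))
    n_ch = data.shape[0]
    axes = np.tile([0.0, 0.0, 1.0], (n_ch, 1))
    positions = np.zeros((n_ch, 3))
    positions[:, 2] = 0.12
    names = [f"CH{i:02d}" for i in range(n_ch)]
    return RawRecording(data=data, fs=fs, channel_names=names,
                        positions=positions, axes=axes, events=events)


@pytest.fixture(scope="session")
def small_schedule():
    return generate_schedule(20, 10, rng=123)


@pytest.fixture(scope="session")
def tiny_dataset(small_schedule):
    """20-task-trial synthetic recording (352 s at 200 Hz, 8 sensors, 4 regions)."""
    array = build_helmet_array(8, 0.12, rng=5)
    model = make_source_model(4)
    return simulate_recording(small_schedule, model, array, BurstSpec(),
                              noise_sd=5e-14, drift_amplitude=2e-12,
                              fs=200.0, rng=7)
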