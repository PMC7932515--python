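import numpy as np
import pytest

import appsth as ap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sam_fixture():
    """A SAM-shaped difference-PSTH-like waveform on an exact-cycle grid."""
    fs = 10000.0
    t = np.arange(5000) / fs  # 0.5 s
    fc, fm = 500.0, 20.0
    d = (1.0 + 0.8 * np.cos(2 * np.pi * fm * t)) * np.cos(2 * np.pi * fc * t)
    return ap.TimeSeries(d, fs)


@pytest.fixture
def poisson_trains(rng):
    """Seeded homogeneous-Poisson spike-train set, 10 trains, ~50 spikes each."""
    dur = 0.5
    trains = [np.sort(rng.uniform(0, dur, rng.poisson(50))) for _ in range(10)]
    return ap.SpikeTrainSet(trains, [1] * 10, dur)
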