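import numpy as np
import pytest

import emgflow as ef


@pytest.fixture(scope="session")
def small_plan():
    """A downsized version of the reference task: 12 gestures, 5 repetitions."""
    return ef.benchmark_plan(n_repetitions=5, seed=7)


@pytest.fixture(scope="session")
def small_recording(small_plan):
    return ef.simulate_recording(small_plan)


@pytest.fixture(scope="session")
def small_windows(small_plan, small_recording):
    """Z-scored, relabeled, segmented windows of the small benchmark."""
    rec = ef.zscore(small_recording)
    rec = ef.TeagerRelabeler().transform(rec)
    scmap = ef.benchmark_superclass_map(small_plan)
    wins = ef.segment(rec, 400, scmap)
    X = np.stack([w.data for w in wins])
    y = np.array([w.label for w in wins])
    return X, y, scmap


@pytest.fixture(scope="session")
def two_tone_recording():
    """Two channels mixing 5 Hz and 20 Hz tones with distinct amplitudes."""
    t = np.arange(1000) / 100.0
    s5, s20 = np.cos(2 * np.pi * 5 * t), np.cos(2 * np.pi * 20 * t)
    signal = np.stack([s5 + 0.5 * s20, 0.7 * s5 + 1.3 * s20], axis=1)
    return ef.MultichannelRecording(signal=signal, fs=100.0,
                                    labels=np.zeros(1000, dtype=int)), s5, s20
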