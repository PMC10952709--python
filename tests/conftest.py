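import numpy as np
import pytest

import szmarkers as sz


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_segment(data, fs=256.0, t0=0.0):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return sz.SignalSegment(data, fs, tuple(f"c{i}" for i in range(data.shape[0])), t0)


@pytest.fixture(scope="session")
def standard_seizure():
    """One seizure with recruitment and suppression plus its ground truth."""
    params = sz.SimulationParams(
        n_channels=12,
        ictal_len=40.0,
        recruited_fraction=0.5,
        suppression_fraction=0.75,
        suppression_len=30.0,
        seed=42,
    )
    return sz.simulate_record(params)


@pytest.fixture(scope="session")
def standard_markers(standard_seizure):
    record, _ = standard_seizure
    return sz.compute_markers(record)


@pytest.fixture(scope="session")
def preprocessed_standard(standard_seizure):
    record, truth = standard_seizure
    proc, removed = sz.preprocess_record(record)
    return proc, truth, removed
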