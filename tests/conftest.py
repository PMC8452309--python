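import numpy as np
import pytest

from qcmfit.hemodynamics import canonical_hrf
from qcmfit.synthetic import (
    DEFAULT_TRUTH,
    NoiseSpec,
    default_sessions,
    simulate_measurement_set,
)

TR = 0.8


@pytest.fixture(scope="session")
def hrf():
    return canonical_hrf(TR)


@pytest.fixture(scope="session")
def small_sessions():
    """Two sessions of two runs each: the full stimulus roster at reduced
    run counts, for fast fitting tests."""
    return default_sessions(seed=11, n_runs=2)


@pytest.fixture(scope="session")
def small_runs(small_sessions):
    return [run for session in small_sessions for run in session.runs]


@pytest.fixture(scope="session")
def noiseless_data(small_sessions, hrf):
    """Noise-free measurement set simulated from the default QCM truth."""
    return simulate_measurement_set(
        DEFAULT_TRUTH, small_sessions, hrf, NoiseSpec(sd=0.0), seed=11
    )


@pytest.fixture(scope="session")
def noiseless_series(noiseless_data):
    return np.concatenate([s for session in noiseless_data for _, s in session])
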