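import numpy as np
import pytest

import npqkin as nk


@pytest.fixture(scope="session")
def crop_schedule():
    return nk.crop_default()


@pytest.fixture(scope="session")
def arabidopsis_schedule():
    return nk.arabidopsis_fluctuating()


@pytest.fixture(scope="session")
def truth():
    return nk.GroundTruth()


@pytest.fixture()
def noiseless_series(truth, crop_schedule):
    trace = nk.trace_from_truth(truth, crop_schedule, noise_sd=0.0, seed=0)
    return nk.npq_series(trace)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
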