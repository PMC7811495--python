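import numpy as np
import pytest

import eropipe as ep


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_sim():
    """12-subject simulation at 10 dB — shared by tests that only need
    a realistic dataset, not the full 68-subject recovery problem."""
    model = ep.make_default_sources(seed=7, snr_db=10.0)
    return ep.simulate_dataset(model, 12)


@pytest.fixture(scope="session")
def small_filtered(small_sim):
    return ep.wavelet_filter(small_sim.dataset)


def make_dataset(data, srate=150.0, t0=-200.0, channels=None, conditions=None):
    """Helper for hand-built datasets in tests."""
    ns, nc, nch, nt = data.shape
    channels = channels or [f"ch{i}" for i in range(nch)]
    conditions = conditions or [f"c{i}" for i in range(nc)]
    times = t0 + np.arange(nt) * 1000.0 / srate
    return ep.ErpDataset(data=data, times=times, srate=srate,
                         channel_labels=channels, condition_labels=conditions)
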