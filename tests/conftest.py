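import numpy as np
import pytest

from nirsconn import montage_io as mio
from nirsconn import preprocess as pp
from nirsconn import synthetic_data as sd


@pytest.fixture(scope="session")
def montage():
    return mio.default_montage()


@pytest.fixture()
def rng():
    return np.random.default_rng(20170419)


@pytest.fixture(scope="session")
def fast_config():
    """Short-duration simulation for unit tests that only need structure."""
    return sd.SimulationConfig(duration_rest_s=240.0, duration_task_s=120.0,
                               task_events=((35.0, 12.0, "gamble"),
                                            (65.0, 12.0, "gamble"),
                                            (95.0, 12.0, "gamble")),
                               artifact_rate_per_min=0.0, seed=7)


def make_series(data_hbo, data_hb=None, fs=50.0, channel_ids=None):
    """HemoTimeSeries from raw arrays, defaulting Hb to -HbO/3."""
    hbo = np.asarray(data_hbo, dtype=float)
    hb = -hbo / 3.0 if data_hb is None else np.asarray(data_hb, dtype=float)
    ids = channel_ids or tuple(range(1, hbo.shape[1] + 1))
    return pp.HemoTimeSeries(hbo=hbo, hb=hb, sampling_rate_hz=fs,
                             channel_ids=tuple(ids))


@pytest.fixture(scope="session")
def preprocessed_subject(fast_config):
    """One preprocessed resting subject shared by read-only tests."""
    rec = sd.simulate_resting_recording(fast_config, "HD01")
    return pp.preprocess_recording(rec)
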