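import numpy as np
import pytest

from zcbat.synthetic import species_presets
from zcbat.zc_data import Pulse


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def myso_model():
    return species_presets()["MYSO"]


def make_pulse(t_us, f_hz, file_id="f"):
    return Pulse(file_id=file_id, t_us=np.asarray(t_us), f_hz=np.asarray(f_hz))


def log_linear_pulse(f_start_khz, f_end_khz, dur_ms, n_dots=21, file_id="f", t0=0):
    """Pulse whose dots lie exactly on a log-linear sweep."""
    t = np.linspace(0.0, dur_ms * 1e3, n_dots)
    frac = t / t[-1]
    f = f_start_khz * 1e3 * (f_end_khz / f_start_khz) ** frac
    return make_pulse(np.round(t).astype(np.int64) + t0, f, file_id)


def random_bat_pulse(rng, model=None):
    from zcbat.synthetic import species_presets, synth_pulse

    model = model or species_presets()["MYSO"]
    return synth_pulse(model, rng)
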