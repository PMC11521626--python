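import numpy as np
import pandas as pd
import pytest

from shearlog import synthio


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Deterministic study conditions with shading off (clean light)."""
    return synthio.SimConfig(shading_prob=0.0, seed=11)


@pytest.fixture(scope="session")
def sim_index(noiseless_cfg):
    return synthio.simulate_index(noiseless_cfg)


@pytest.fixture(scope="session")
def one_bird_year(noiseless_cfg, sim_index):
    """Track + light for one clean bird-year (shared; read-only)."""
    positions, phen, winter = synthio.simulate_track(noiseless_cfg, 0, 2008, sim_index)
    light = synthio.simulate_light(positions, noiseless_cfg)
    return {"positions": positions, "phenology": phen, "winter": winter, "light": light}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def square_wave_trace(date="2009-06-01", rise="06:00", fall="18:00",
                      low=0.0, high=64.0, step_min=10):
    """Light trace jumping through the threshold at exact clock times."""
    times = pd.date_range(f"{date} 00:00", f"{date} 23:50", freq=f"{step_min}min")
    light = np.where((times >= pd.Timestamp(f"{date} {rise}"))
                     & (times < pd.Timestamp(f"{date} {fall}")), high, low)
    return pd.DataFrame({"timestamp": times, "light": light})
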