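import numpy as np
import pytest

from rwahome.config import RunConfig
from rwahome.hypnogram import Hypnogram
from rwahome.io import load_table4


@pytest.fixture(scope="session")
def table4():
    return load_table4()


@pytest.fixture(scope="session")
def table4_groups(table4):
    c = table4.loc[table4["group"] == "C", "rwa_pct"].to_numpy()
    b = table4.loc[table4["group"] == "B", "rwa_pct"].to_numpy()
    return c, b


@pytest.fixture
def short_cfg():
    """A 2-hour night at the device rate: enough REM to score, quick to run."""
    return RunConfig(night_len_min=120.0, seed=0)


@pytest.fixture
def toy_hypnogram():
    """16 epochs: 4 W, 2 N1, 4 N2, 2 N3, 4 REM; lights span everything."""
    stages = ["W"] * 4 + ["N1"] * 2 + ["N2"] * 4 + ["N3"] * 2 + ["REM"] * 4
    return Hypnogram(np.array(stages, dtype=object))
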