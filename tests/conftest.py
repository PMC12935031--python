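import numpy as np
import pandas as pd
import pytest

from terracarbon.config import DeltaSocModel, WorldConfig
from terracarbon.synthetic import generate_world


@pytest.fixture(scope="session")
def demo_world():
    """Default 14-site synthetic study, shared across tests (read-only)."""
    return generate_world(WorldConfig(seed=0))


@pytest.fixture
def noise_free_config():
    """World with every stochastic knob at zero (deterministic structure)."""
    return WorldConfig(
        seed=0,
        delta_soc_model=DeltaSocModel(slope=0.0, intercept=0.0, site_sd=0.0),
        soc_noise_sd=0.0, geochem_noise_sd=0.0, bd_noise_sd=0.0,
        pixel_sd=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_profile(depths, socs, bds, clay=20.0, silt=35.0, profile_id="P1"):
    """Horizon table helper: depths are layer edges."""
    tops, bots = depths[:-1], depths[1:]
    return pd.DataFrame({
        "site_id": "S01",
        "profile_id": profile_id,
        "position": "control",
        "depth_top": tops,
        "depth_bottom": bots,
        "soc": socs,
        "clay": clay,
        "silt": silt,
        "bd_measured": bds,
    })
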