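import numpy as np
import pytest
from hypothesis import settings

from aquasrc import synthetic

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from aquasrc.forcing import SiteConfig
from aquasrc.soil_water import SoilParams


@pytest.fixture(scope="session")
def site() -> SiteConfig:
    return SiteConfig(latitude=51.1, elevation=6.25)


@pytest.fixture(scope="session")
def soil() -> SoilParams:
    return synthetic.default_soil()


@pytest.fixture(scope="session")
def coppice_params():
    """First-year-after-coppice crop parameter set."""
    return synthetic.COPPICE_YEAR_PARAMS


@pytest.fixture(scope="session")
def resprout_params():
    """Second-year (resprout) crop parameter set."""
    return synthetic.RESPROUT_YEAR_PARAMS


@pytest.fixture(scope="session")
def synth_cfg() -> synthetic.SynthConfig:
    return synthetic.SynthConfig(seed=0)


@pytest.fixture(scope="session")
def campaign(synth_cfg):
    """Full 4-year synthetic campaign: forcing, truth run, observations."""
    weather = synthetic.gen_weather(synth_cfg)
    water_table = synthetic.gen_water_table(synth_cfg)
    schedule = synthetic.default_schedule(synth_cfg)
    soil = synthetic.default_soil()
    site = synthetic.default_site(synth_cfg)
    truth = synthetic.truth_run(schedule, soil, weather, site, water_table)
    observations = synthetic.gen_observations(truth, synth_cfg)
    return {
        "cfg": synth_cfg, "weather": weather, "water_table": water_table,
        "schedule": schedule, "soil": soil, "site": site,
        "truth": truth, "observations": observations,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
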