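import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from wetlandch4 import ch4_core, hydrology, scenario_forge as sf

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline_climate_2y() -> pd.DataFrame:
    """Two years of seeded baseline weather for a single site."""
    spec = sf.scenario("baseline", seed=7, years=(2001, 2002))
    return sf.generate_climate_series(spec)


@pytest.fixture(scope="session")
def baseline_climate_decade() -> pd.DataFrame:
    spec = sf.scenario("baseline", seed=1, years=(2001, 2010))
    return sf.generate_climate_series(spec)


@pytest.fixture(scope="session")
def carex_wt(baseline_climate_2y) -> pd.DataFrame:
    return hydrology.simulate_water_table(
        baseline_climate_2y, hydrology.EHM_PRESETS["carex"])


@pytest.fixture
def soil() -> ch4_core.SoilProfile:
    return ch4_core.SoilProfile(sand=25.0, som=150.0, bulk_density=0.6)


@pytest.fixture
def carex_traits() -> ch4_core.VegetationTraits:
    return ch4_core.vegetation_traits("carex")
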