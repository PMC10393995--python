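import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from climstress.data_io import DailySeries, season_labels
from climstress.indices import build_threshold_climatology
from climstress.synthetic import WeatherGenParams, generate_daily_weather


@pytest.fixture(scope="session")
def small_weather() -> DailySeries:
    """Five-season synthetic daily record, fixed seed."""
    return generate_daily_weather(WeatherGenParams(n_seasons=5, seed=11))


@pytest.fixture(scope="session")
def small_seasons() -> list[str]:
    return season_labels(1986, 5)


@pytest.fixture(scope="session")
def small_clim(small_weather, small_seasons):
    return build_threshold_climatology(small_weather, small_seasons)


@pytest.fixture(scope="session")
def study_weather() -> DailySeries:
    """Full-length 30-season record at the default generator settings."""
    return generate_daily_weather(WeatherGenParams(n_seasons=30, seed=7))


@pytest.fixture(scope="session")
def study_seasons() -> list[str]:
    return season_labels(1986, 30)


@pytest.fixture(scope="session")
def study_clim(study_weather, study_seasons):
    return build_threshold_climatology(study_weather, study_seasons)


def make_daily(dates: pd.DatetimeIndex, tmax, precip) -> DailySeries:
    tmax = np.broadcast_to(np.asarray(tmax, float), len(dates))
    precip = np.broadcast_to(np.asarray(precip, float), len(dates))
    return DailySeries(
        pd.DataFrame({"tmax_c": tmax, "precip_mm": precip}, index=dates)
    )
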