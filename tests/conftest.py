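from datetime import date

import numpy as np
import pytest

import somrisk as sr


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free, storm-free summer regime for exact arithmetic checks."""
    return sr.SeasonParams(
        season_label="summer", ap_mean=1003.0, ap_sd=0.0,
        t_mean=29.0, t_sd=0.0, t_diurnal_amp=0.0,
        ws_mean=2.0, ws_sd=0.0, wd_regime="diurnal_rotation",
        storm_rate=0.0, storm_intensity_mean=1.0,
    )


@pytest.fixture(scope="session")
def quiet_series(quiet_params):
    return sr.simulate_station(quiet_params, n_days=10,
                               start_date=date(2017, 6, 1), seed=0)


@pytest.fixture(scope="session")
def small_study():
    """A reduced study: 3 summer + 2 non-summer events."""
    stations, events = sr.simulate_study(seed=42, n_summer=3, n_non_summer=2)
    return stations, events


@pytest.fixture(scope="session")
def small_matrix(small_study):
    stations, events = small_study
    return sr.normalize(sr.bundle_events(stations, events))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
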