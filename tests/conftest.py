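import numpy as np
import pandas as pd
import pytest

from heatexposure import simulate, wbgt


@pytest.fixture(scope="session")
def small_config():
    """A 3-settlement, 10-day network: fast but structurally complete."""
    return simulate.SimulationConfig(
        n_settlements=3,
        outdoor_per_settlement=5,
        houses_per_settlement=4,
        pairs_per_house=3,
        start="2019-03-01",
        end="2019-03-10",
        seed=7,
    )


@pytest.fixture(scope="session")
def small_network(small_config):
    return simulate.simulate_network(small_config)


@pytest.fixture(scope="session")
def station_records(small_config, small_network):
    _, truth = small_network
    return simulate.simulate_station(small_config, truth)


def make_records(rows):
    """Build a logger-record frame from (logger, site, placement, house,
    hour-offset, T, RH) tuples; hours count from 2019-03-01 00:00 local."""
    base = pd.Timestamp("2019-03-01 00:00").tz_localize(wbgt.LOCAL_TZ)
    return pd.DataFrame(
        [
            {
                "logger_id": lid,
                "site_id": site,
                "placement": placement,
                "house_id": house,
                "timestamp": base + pd.Timedelta(hours=h),
                "temperature_c": t,
                "rh_pct": rh,
            }
            for lid, site, placement, house, h, t, rh in rows
        ]
    )


def make_series(hours, values, unit="U1"):
    """WBGT/TW series for exposure tests; ``values`` may contain None."""
    base = pd.Timestamp("2019-03-01 00:00").tz_localize(wbgt.LOCAL_TZ)
    return pd.DataFrame(
        {
            "unit_id": unit,
            "timestamp": [base + pd.Timedelta(hours=h) for h in hours],
            "wbgt_c": [np.nan if v is None else v for v in values],
            "tw_c": [np.nan if v is None else v for v in values],
        }
    )
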