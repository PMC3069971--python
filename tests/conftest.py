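import numpy as np
import pandas as pd
import pytest

import runoffscreen as rs


@pytest.fixture(scope="session")
def cotton():
    return rs.get_scenario("cotton")


@pytest.fixture(scope="session")
def weather6(cotton):
    """Six years of Mediterranean weather with the cotton irrigation calendar."""
    cfg = rs.default_weather_config(cotton, n_years=6, seed=11)
    return rs.generate_weather(cfg)


@pytest.fixture(scope="session")
def cotton_matrices(cotton, weather6):
    """A small stochastic derivation shared across regression tests."""
    design = rs.MonteCarloDesign(n_runs=120, seed=3)
    return rs.run_batch(design, cotton, weather6)


@pytest.fixture()
def annual_schedule_maker():
    def make(weather, rate=0.1, month_day="06-15"):
        years = sorted(set(weather.dates.year))
        return [
            rs.ApplicationEvent(date=pd.Timestamp(f"{y}-{month_day}"),
                                rate_kg_per_ha=rate)
            for y in years
        ]
    return make
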