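import numpy as np
import pandas as pd
import pytest

import burnflow as bf


@pytest.fixture(scope="session")
def small_case():
    """One 12-year synthetic watershed with an active fire effect."""
    weather = bf.WeatherParams()
    hydro = bf.HydroParams()
    daily = bf.generate_daily_weather(weather, 12, seed=42)
    daily["SWE"] = bf.simulate_snowpack(daily, hydro)
    fire = bf.generate_fire_event(
        0.30,
        {"unburned": 0.10, "low": 0.30, "moderate": 0.40, "high": 0.15,
         "greenness": 0.05},
        daily.index[0] + pd.DateOffset(years=6),
    )
    q, truth = bf.simulate_flow(daily, hydro, fire, bf.FireEffectParams(),
                                seed=43)
    daily = daily.copy()
    daily["Q"] = q
    return {"daily": daily, "fire": fire, "hydro": hydro, "truth": truth}


@pytest.fixture(scope="session")
def monthly_series(small_case):
    monthly = bf.monthly_from_daily(small_case["daily"])
    return monthly


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
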