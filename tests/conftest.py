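import numpy as np
import pytest

import riceclim as rc


@pytest.fixture(scope="session")
def calendars2():
    return rc.example_calendars(2)


@pytest.fixture(scope="session")
def calendars3():
    return rc.example_calendars(3)


@pytest.fixture(scope="session")
def weather52():
    """53 weather years (1960-2012) covering 52 census years."""
    return rc.generate_weather(rc.WeatherGenSpec(seed=11))


@pytest.fixture(scope="session")
def crop_truth(weather52, calendars2):
    """Synthetic census series with known sparse climate signal."""
    cs, truth = rc.generate_crop_series(
        weather52, calendars2, rc.ResponseSpec(seed=11)
    )
    return cs, truth


@pytest.fixture(scope="session")
def area_ensemble(crop_truth):
    """Rolling-origin elastic-net ensemble on the area anomalies.

    Session-scoped: the 27 CV fits are the slowest object in the suite and
    several tests inspect them.
    """
    cs, truth = crop_truth
    X = truth["predictors"]
    anoms = rc.detrend_crop_series(cs)
    fits, preds = rc.rolling_origin_ensemble(
        X, anoms["area"].anomaly_pct, seed=11, response="area"
    )
    return {"X": X, "anoms": anoms, "fits": fits, "preds": preds,
            "truth": truth}
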