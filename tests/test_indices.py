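import numpy as np
import pandas as pd
import pytest

import riceclim as rc
from riceclim.calendar import PeriodWindow
from riceclim.indices import (
    INDEX_ORDER,
    PRECIP_INDICES,
    TEMP_INDICES,
    PercentileThresholds,
    _precip_index_from_days,
    _temp_index_from_days,
)

from oracle_indices import oracle_index


def _thr(tx10=-1e9, tx90=1e9, tn10=-1e9, tn90=1e9, r95=0.0, r99=0.0):
    return PercentileThresholds(tx10=tx10, tx90=tx90, tn10=tn10, tn90=tn90,
                                r95=r95, r99=max(r95, r99), base_period=(0, 0))


WORKED_PRECIP = np.array([0, 0.5, 2, 0, 0, 0, 15, 3, 0.9, 0], dtype=float)


@pytest.mark.parametrize(
    "name,expected",
    [
        ("CDD", 3.0), ("CWD", 2.0), ("R10mm", 1.0), ("PRCPTOT", 20.0),
        ("RX1day", 15.0), ("RX5day", 18.9), ("SDII", 20.0 / 3.0),
        ("R20mm", 0.0), ("PAVG", 2.14),
    ],
)
def test_worked_ten_day_precipitation_example(name, expected):
    """Hand-derived values on the 10-day example window."""
    val = _precip_index_from_days(name, WORKED_PRECIP, _thr())
    assert val == pytest.approx(expected)


def test_precip_edge_conventions():
    """All-dry windows and single-wet-day collapse behave as documented."""
    dry = np.zeros(30)
    assert _precip_index_from_days("CDD", dry, None) == 30
    assert _precip_index_from_days("CWD", dry, None) == 0
    assert _precip_index_from_days("PRCPTOT", dry, None) == 0
    assert _precip_index_from_days("SDII", dry, None) == 0  # undefined -> 0
    one = np.zeros(20)
    one[7] = 100.0
    thr = _thr(r95=50.0, r99=50.0)
    for name in ("R95pTOT", "R99pTOT", "PRCPTOT", "RX1day"):
        assert _precip_index_from_days(name, one, thr) == 100.0


def test_temp_threshold_counting():
    tx = np.array([30, 31, 35, 29, 28, 33, 36], dtype=float)
    tn = np.array([-1, 0.5, 2, -3], dtype=float)
    assert _temp_index_from_days("TXx", tx, tx, None) == 36
    assert _temp_index_from_days("TXn", tx, tx, None) == 28
    assert _temp_index_from_days("SU", tx, tx, None) == 7
    assert _temp_index_from_days("FD", tn, tn, None) == 2
    assert _temp_index_from_days("TR", tn, tn, None) == 0


def test_percentile_count_uses_strict_inequality():
    """Days exactly at the threshold are not counted (ETCCDI convention)."""
    tx = np.full(10, 20.0)
    thr = _thr(tx10=20.0, tx90=20.0)
    assert _temp_index_from_days("TX10p", tx, tx, thr) == 0.0
    assert _temp_index_from_days("TX90p", tx, tx, thr) == 0.0


def test_thresholds_linear_interpolation_quantiles(weather52, calendars2):
    """tx90 of pooled values 20..29 is 28.1 under linear interpolation."""
    pooled = np.arange(20.0, 30.0)
    assert np.quantile(pooled, 0.9, method="linear") == pytest.approx(28.1)
    sowing = rc.derive_periods(calendars2[0])[0]
    t = rc.compute_percentile_thresholds(weather52, sowing, (1961, 1990))
    assert t.tx10 < t.tx90 and t.tn10 < t.tn90 and t.r95 <= t.r99
    # quantiles are invariant to duplicating the base sample
    t2 = rc.compute_percentile_thresholds(weather52, sowing, (1961, 1990))
    assert t == t2


def test_insufficient_wet_days_error():
    dates = pd.date_range("2000-01-01", "2003-12-31", freq="D")
    w = rc.DailyWeather("dryland", dates, np.full(len(dates), 30.0),
                        np.full(len(dates), 20.0), np.zeros(len(dates)))
    win = PeriodWindow("sowing", 4, 6, False, 4)
    with pytest.raises(ValueError, match="insufficient base sample"):
        rc.compute_percentile_thresholds(w, win, (2001, 2003))


def test_oracle_equivalence_on_random_windows():
    """Every index matches an explicit-loop reimplementation on 200
    randomized 30-150 day windows."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(30, 151))
        tmean = rng.normal(25, 4, n)
        drange = rng.uniform(4, 12, n)
        tx, tn = tmean + drange / 2, tmean - drange / 2
        p = np.where(rng.random(n) < 0.4, rng.gamma(0.7, 14, n), 0.0)
        wet = p[p >= 1.0]
        r95 = np.quantile(wet, 0.95) if len(wet) else 0.0
        thr = PercentileThresholds(
            tx10=np.quantile(tx, 0.1), tx90=np.quantile(tx, 0.9),
            tn10=np.quantile(tn, 0.1), tn90=np.quantile(tn, 0.9),
            r95=r95, r99=np.quantile(wet, 0.99) if len(wet) else 0.0,
            base_period=(0, 0),
        )
        for name in INDEX_ORDER:
            if name in PRECIP_INDICES:
                got = _precip_index_from_days(name, p, thr)
            else:
                got = _temp_index_from_days(name, tx, tn, thr)
            want = oracle_index(name, tx, tn, p, thr)
            assert got == pytest.approx(want), name


def test_index_inequality_invariants():
    """Nested-subset and bound invariants hold on random windows."""
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = int(rng.integers(30, 120))
        p = np.where(rng.random(n) < 0.5, rng.gamma(0.8, 10, n), 0.0)
        tx = rng.normal(30, 3, n)
        tn = tx - rng.uniform(3, 10, n)
        wet = p[p >= 1.0]
        thr = _thr(
            tx10=np.quantile(tx, 0.1), tx90=np.quantile(tx, 0.9),
            tn10=np.quantile(tn, 0.1), tn90=np.quantile(tn, 0.9),
            r95=np.quantile(wet, 0.95) if len(wet) else 0.0,
            r99=np.quantile(wet, 0.99) if len(wet) else 0.0,
        )
        v = {k: (_precip_index_from_days(k, p, thr) if k in PRECIP_INDICES
                 else _temp_index_from_days(k, tx, tn, thr))
             for k in INDEX_ORDER}
        assert v["R99pTOT"] <= v["R95pTOT"] <= v["PRCPTOT"]
        assert v["RX5day"] >= v["RX1day"]
        assert 0 <= v["TX10p"] <= 100 and 0 <= v["TX90p"] <= 100
        assert v["CDD"] + v["CWD"] <= n
        # shifting all temperatures shifts extremes, leaves DTR unchanged
        c = 2.5
        assert _temp_index_from_days("TXx", tx + c, tn + c, thr) == \
            pytest.approx(v["TXx"] + c)
        assert _temp_index_from_days("TNn", tx + c, tn + c, thr) == \
            pytest.approx(v["TNn"] + c)
        assert _temp_index_from_days("DTR", tx + c, tn + c, thr) == \
            pytest.approx(v["DTR"])


def test_unknown_index_rejected(weather52, calendars2):
    win = rc.derive_periods(calendars2[0])[0]
    with pytest.raises(ValueError, match="unknown"):
        rc.compute_index("BOGUS", weather52, win, 1990)


def test_predictor_matrix_shape_and_order(weather52, calendars2, calendars3):
    """162 columns for two seasons, 243 for three; documented column order."""
    X2 = rc.build_predictor_matrix(weather52, calendars2, range(1990, 1995))
    X3 = rc.build_predictor_matrix(weather52, calendars3, range(1990, 1995))
    assert X2.shape == (5, 162)
    assert X3.shape == (5, 243)
    assert list(X2.columns[:2]) == [
        ("wet", "sowing", "RX1day"), ("wet", "sowing", "RX5day")]
    seasons = X3.columns.get_level_values("season")
    assert list(dict.fromkeys(seasons)) == ["wet_early", "wet", "dry"]


def test_predictor_matrix_drops_uncovered_years(weather52, calendars2, caplog):
    """Years whose windows exceed the record are dropped, not imputed."""
    import logging

    with caplog.at_level(logging.WARNING, logger="riceclim.indices"):
        X = rc.build_predictor_matrix(
            weather52, calendars2, range(2010, 2016))
    assert list(X.index) == [2010, 2011, 2012]
    assert "dropped" in caplog.text
    assert not X.isna().any().any()


def test_predictor_matrix_deterministic_rows(calendars2):
    """Identical weather in consecutive non-leap years gives identical rows."""
    dates = pd.date_range("2001-01-01", "2003-12-31", freq="D")
    doy = dates.dayofyear.values.astype(float)
    rng = np.random.default_rng(0)
    one_year = {
        "t": 25 + 3 * np.cos(2 * np.pi * doy[:365] / 365),
        "p": np.where(rng.random(365) < 0.4, rng.gamma(0.8, 10, 365), 0.0),
    }
    t = np.tile(one_year["t"], 3)
    p = np.tile(one_year["p"], 3)
    w = rc.DailyWeather("rep", dates, t + 5, t - 5, p)
    X = rc.build_predictor_matrix(w, calendars2, [2002, 2003])
    assert np.allclose(X.loc[2002].values, X.loc[2003].values)
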