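"""Synthetic daily weather, crop calendars and census series with known
ground truth, so every pipeline stage is testable without external data.

The weather generator emulates a ~52-year daily monsoon-climate record: a
sinusoidal annual temperature cycle with AR(1) day-to-day noise, a diurnal
range with daily jitter, and precipitation as a monthly-varying Bernoulli
occurrence process with gamma-distributed wet-day amounts. Optional linear
warming and precipitation trends and constant model biases support the
scenario-projection and bias-correction stages. Random streams are split
per variable and per year, so lengthening the record never perturbs
earlier years.

Census series are built by the same model the anomaly regressions assume:
annual value = smooth positive trend x (1 + anomaly/100), where the true
anomaly is a sparse linear combination of standardized climate predictors
plus Gaussian noise. By default the climate signal enters through
sowing-period indices of the wet/rainfed season — the regime in which
pre-planting rainfall governs how much area gets planted — so that signal
placement is recoverable end to end.

The generator does not attempt physically realistic monsoon dynamics,
spatial correlation between locations, or interannual persistence beyond
the AR(1) day scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calendar import SeasonCalendar, example_calendars
from .detrend import CropSeries
from .indices import DailyWeather, build_predictor_matrix

#: monthly wet-day probability of a wet-season-dominated monsoon climate
DEFAULT_WET_PROB = (0.10, 0.10, 0.15, 0.25, 0.50, 0.65,
                    0.70, 0.70, 0.60, 0.40, 0.20, 0.10)

_VAR_CODE = {"temp": 0, "range": 1, "occurrence": 2, "amount": 3, "onset": 4}


@dataclass(frozen=True)
class WeatherGenSpec:
    """Parameters of the synthetic daily weather generator."""

    # 53 weather years starting 1960 give 52 census years (1961-2012): the
    # first year only supplies the lookback months of wrapped/sowing windows
    seed: int = 0
    start_year: int = 1960
    n_years: int = 53
    temp_mean: float = 27.0          # degC annual mean
    temp_amplitude: float = 3.0      # degC seasonal half-range
    temp_phase_doy: float = 120.0    # day of year of the seasonal maximum
    ar1_phi: float = 0.7             # day-to-day temperature persistence
    ar1_sd: float = 1.2              # degC innovation sd
    diurnal_range_mean: float = 9.0  # degC tmax - tmin
    diurnal_range_sd: float = 1.5    # daily jitter of the diurnal range
    wet_prob_by_month: tuple = DEFAULT_WET_PROB
    gamma_shape: float = 0.8         # wet-day amount shape
    gamma_scale: float = 12.0        # wet-day amount scale, mm
    onset_jitter_sd: float = 0.0     # monsoon-onset shift sd, days
    warming_per_decade: float = 0.0  # degC/decade linear trend
    precip_trend_per_decade: float = 0.0  # %/decade multiplicative trend
    bias_temp: float = 0.0           # constant model temperature bias, degC
    bias_precip_ratio: float = 1.0   # constant model precipitation ratio

    def __post_init__(self) -> None:
        if not all(0.0 <= p <= 1.0 for p in self.wet_prob_by_month):
            raise ValueError("wet-day probabilities must lie in [0, 1]")
        if len(self.wet_prob_by_month) != 12:
            raise ValueError("need 12 monthly wet-day probabilities")
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("gamma parameters must be positive")
        if not -1.0 < self.ar1_phi < 1.0:
            raise ValueError("AR(1) phi must lie in (-1, 1)")
        if self.ar1_sd < 0 or self.diurnal_range_sd < 0 or self.onset_jitter_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.bias_precip_ratio <= 0:
            raise ValueError("precipitation bias ratio must be positive")


def _year_rng(spec: WeatherGenSpec, year: int, var: str) -> np.random.Generator:
    """Independent stream per (seed, year, variable)."""
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, year, _VAR_CODE[var]])
    )


def generate_weather(spec: WeatherGenSpec, location_id: str = "synth") -> DailyWeather:
    """Generate a reproducible daily tmax/tmin/precip record.

    tmean = seasonal sinusoid + warming trend + AR(1) noise; tmax/tmin =
    tmean +/- half the (jittered) diurnal range; precip = Bernoulli(monthly
    wet probability) x Gamma(shape, scale), with optional monsoon-onset
    jitter shifting the occurrence seasonality and a multiplicative amount
    trend. Constant biases (for bias-correction testing) are applied last.
    """
    y0 = spec.start_year
    all_t, all_tmax, all_tmin, all_pr = [], [], [], []
    dates = pd.date_range(f"{y0}-01-01", f"{y0 + spec.n_years - 1}-12-31", freq="D")
    monthly_p = np.asarray(spec.wet_prob_by_month, dtype=float)

    for yr in range(y0, y0 + spec.n_years):
        ydates = dates[(dates.year == yr)]
        nd = len(ydates)
        doy = ydates.dayofyear.values.astype(float)
        frac_years = (yr - y0) + (doy - 1) / 365.25

        # --- temperature ---
        rng_t = _year_rng(spec, yr, "temp")
        cyc = spec.temp_mean + spec.temp_amplitude * np.cos(
            2 * np.pi * (doy - spec.temp_phase_doy) / 365.25
        )
        trend = spec.warming_per_decade / 10.0 * frac_years
        eps = rng_t.normal(0.0, spec.ar1_sd, nd)
        noise = np.empty(nd)
        stat_sd = spec.ar1_sd / np.sqrt(1 - spec.ar1_phi**2)
        noise[0] = rng_t.normal(0.0, stat_sd)  # stationary start each year
        for i in range(1, nd):
            noise[i] = spec.ar1_phi * noise[i - 1] + eps[i]
        tmean = cyc + trend + noise

        rng_r = _year_rng(spec, yr, "range")
        drange = np.clip(
            rng_r.normal(spec.diurnal_range_mean, spec.diurnal_range_sd, nd), 1.0, None
        )

        # --- precipitation ---
        if spec.onset_jitter_sd > 0:
            rng_o = _year_rng(spec, yr, "onset")
            shift = rng_o.normal(0.0, spec.onset_jitter_sd)
        else:
            shift = 0.0
        # daily wet probability: monthly curve interpolated on day of year
        month_mid = (np.arange(12) + 0.5) * 365.25 / 12.0
        p_daily = np.interp(
            (doy - shift) % 365.25, month_mid, monthly_p, period=365.25
        )
        rng_occ = _year_rng(spec, yr, "occurrence")
        wet = rng_occ.random(nd) < p_daily
        rng_amt = _year_rng(spec, yr, "amount")
        amounts = rng_amt.gamma(spec.gamma_shape, spec.gamma_scale, nd)
        amt_trend = 1.0 + spec.precip_trend_per_decade / 100.0 / 10.0 * frac_years
        precip = np.where(wet, amounts * np.maximum(amt_trend, 0.0), 0.0)

        all_t.append(tmean)
        all_tmax.append(tmean + drange / 2.0)
        all_tmin.append(tmean - drange / 2.0)
        all_pr.append(precip)

    tmax = np.concatenate(all_tmax) + spec.bias_temp
    tmin = np.concatenate(all_tmin) + spec.bias_temp
    precip = np.concatenate(all_pr) * spec.bias_precip_ratio
    return DailyWeather(
        location_id=location_id, dates=dates, tmax=tmax, tmin=tmin, precip=precip
    )


def generate_scenario_weather(
    spec: WeatherGenSpec, location_id: str = "scenario"
) -> tuple[DailyWeather, DailyWeather]:
    """Scenario record with trends/bias, paired with its unbiased truth.

    The truth shares the generator parameters (and random streams) but has
    the constant biases removed, so bias-correction closure can be checked
    exactly.
    """
    biased = generate_weather(spec, location_id=location_id)
    truth_spec = replace(spec, bias_temp=0.0, bias_precip_ratio=1.0)
    truth = generate_weather(truth_spec, location_id=f"{location_id}_truth")
    return biased, truth


# ---------------------------------------------------------------------------
# Census series with known climate response
# ---------------------------------------------------------------------------

#: default true standardized effects: pre-planting dry spells shrink planted
#: area, pre-planting rain totals expand it, sowing-time heat shrinks it
DEFAULT_TRUE_COEF = {
    ("wet", "sowing", "CDD"): -2.0,
    ("wet", "sowing", "PRCPTOT"): 1.5,
    ("wet", "sowing", "TXx"): -1.0,
}


@dataclass(frozen=True)
class ResponseSpec:
    """Ground-truth generating model for an annual census response."""

    seed: int = 0
    response: str = "area"
    trend_base: float = 1.0e6        # level in the first year (ha or t/ha)
    trend_growth: float = 0.010      # exponential growth per year
    true_coef: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_COEF))
    noise_sd: float = 0.8            # anomaly noise, percentage points

    def __post_init__(self) -> None:
        if self.trend_base <= 0:
            raise ValueError("trend must be positive")
        if len(self.true_coef) > 10:
            raise ValueError("at most 10 nonzero true coefficients")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")

    def trend(self, years: np.ndarray) -> np.ndarray:
        t = np.asarray(years, dtype=float)
        return self.trend_base * np.exp(self.trend_growth * (t - t[0]))


def true_anomalies(
    X: pd.DataFrame, rspec: ResponseSpec
) -> tuple[np.ndarray, np.ndarray]:
    """(true climate-driven anomaly, noisy anomaly) in % for each year of X.

    Predictor columns are standardized over the full record; the climate
    signal is the sparse linear combination given by ``true_coef``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([rspec.seed, 97]))
    signal = np.zeros(len(X))
    for key, c in rspec.true_coef.items():
        if key not in X.columns:
            raise KeyError(f"true-coefficient column {key} not in predictor matrix")
        col = X[key].to_numpy(dtype=float)
        sd = col.std(ddof=0)
        if sd == 0:
            raise ValueError(f"true-coefficient column {key} has zero variance")
        signal += c * (col - col.mean()) / sd
    noise = rng.normal(0.0, rspec.noise_sd, len(X))
    return signal, signal + noise


def generate_crop_series(
    w: DailyWeather,
    calendars: list[SeasonCalendar],
    area_spec: ResponseSpec,
    yield_spec: ResponseSpec | None = None,
    years: range | None = None,
) -> tuple[CropSeries, dict]:
    """Annual census series whose anomalies follow a known climate signal.

    Returns the CropSeries together with a truth dict holding the predictor
    matrix, the true (noise-free) and realized anomalies per response, and
    the true coefficients.
    """
    if years is None:
        y0, y1 = w.years
        years = range(y0 + 1, y1 + 1)  # first year reserved for lookback months
    X = build_predictor_matrix(w, calendars, years)
    yrs = X.index.to_numpy()

    if yield_spec is None:
        yield_spec = ResponseSpec(
            seed=area_spec.seed + 1,
            response="yield",
            trend_base=3.0,
            trend_growth=0.015,
            true_coef={
                ("wet", "late_growing", "TXx"): -1.5,
                ("wet", "late_growing", "R95pTOT"): -1.0,
                ("wet", "early_growing", "PRCPTOT"): 1.0,
            },
            noise_sd=area_spec.noise_sd,
        )

    truth: dict = {"predictors": X, "years": yrs}
    values = {}
    for rspec in (area_spec, yield_spec):
        sig, anom = true_anomalies(X, rspec)
        trend = rspec.trend(yrs)
        values[rspec.response] = trend * (1.0 + anom / 100.0)
        truth[rspec.response] = {
            "true_signal_pct": sig,
            "true_anomaly_pct": anom,
            "trend": trend,
            "true_coef": dict(rspec.true_coef),
        }
    cs = CropSeries(
        unit_id=w.location_id, years=yrs,
        area=values["area"], yield_=values["yield"],
    )
    return cs, truth


# ---------------------------------------------------------------------------
# Fixture writer
# ---------------------------------------------------------------------------

def write_fixture_bundle(
    outdir: str | Path,
    seed: int = 0,
    n_seasons: int = 2,
    n_years: int = 53,
) -> dict:
    """Emit weather CSV, census CSV, calendar YAML and a truth JSON.

    The bundle is the packaged end-to-end fixture consumed by the test
    suite and the command-line pipeline.
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wspec = WeatherGenSpec(seed=seed, n_years=n_years)
    w = generate_weather(wspec)
    cals = example_calendars(n_seasons)
    cs, truth = generate_crop_series(w, cals, ResponseSpec(seed=seed))

    w.to_csv(outdir / "weather.csv")
    pd.DataFrame(
        {"unit_id": cs.unit_id, "year": cs.years,
         "area_ha": cs.area, "yield_t_ha": cs.yield_}
    ).to_csv(outdir / "census.csv", index=False)
    cal_cfg = {
        "synthland": [
            {"name": c.season_name, "class": c.season_class,
             "planting": list(c.planting_window),
             "harvesting": list(c.harvesting_window)}
            for c in cals
        ]
    }
    with open(outdir / "calendars.yaml", "w") as fh:
        yaml.safe_dump(cal_cfg, fh)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                resp: {
                    "true_coef": {"|".join(k): v
                                  for k, v in truth[resp]["true_coef"].items()},
                    "true_anomaly_pct": truth[resp]["true_anomaly_pct"].tolist(),
                    "true_signal_pct": truth[resp]["true_signal_pct"].tolist(),
                    "years": truth["years"].tolist(),
                }
                for resp in ("area", "yield")
            },
            fh,
        )
    return {"weather": w, "census": cs, "calendars": cals, "truth": truth,
            "paths": {k: str(outdir / f) for k, f in
                      [("weather", "weather.csv"), ("census", "census.csv"),
                       ("calendars", "calendars.yaml"), ("truth", "truth.json")]}}
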