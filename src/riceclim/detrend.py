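"""Double-filter detrending of annual area/yield series and anomaly summaries.

Census area, yield and production series mix slow non-climatic drivers
(demand, land use, prices, technology) with year-to-year climate shocks. The
long-term trend is estimated by a double filter — a centred 7-year moving
average followed by LOWESS (span f = 0.5, local linear, no robustifying
iterations) — and the climate-attributable signal is the percentage anomaly

    anomaly_pct = 100 * (value - trend) / trend.

Area and yield are always detrended separately so their trends can differ;
production anomalies come from detrending the production series itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess


@dataclass
class CropSeries:
    """Annual census record for one administrative unit."""

    unit_id: str
    years: np.ndarray
    area: np.ndarray    # harvested area, ha
    yield_: np.ndarray  # t/ha

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.area = np.asarray(self.area, dtype=float)
        self.yield_ = np.asarray(self.yield_, dtype=float)
        if not (len(self.years) == len(self.area) == len(self.yield_)):
            raise ValueError("years/area/yield lengths differ")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be contiguous")
        if np.any(self.area <= 0) or np.any(self.yield_ <= 0):
            raise ValueError("area and yield must be positive")

    @property
    def production(self) -> np.ndarray:
        """Production in tonnes (area x yield)."""
        return self.area * self.yield_

    @classmethod
    def from_csv(cls, path, unit_id: str | None = None) -> "CropSeries":
        """Read a (unit_id, year, area_ha, yield_t_ha) census CSV."""
        df = pd.read_csv(path)
        if unit_id is not None:
            df = df[df["unit_id"] == unit_id]
        else:
            unit_id = str(df["unit_id"].iloc[0])
        df = df.sort_values("year")
        return cls(unit_id, df["year"].values, df["area_ha"].values,
                   df["yield_t_ha"].values)


@dataclass
class AnomalySeries:
    """Percentage departures of an annual series from its long-term trend."""

    years: np.ndarray
    trend: np.ndarray
    anomaly_pct: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.trend = np.asarray(self.trend, dtype=float)
        self.anomaly_pct = np.asarray(self.anomaly_pct, dtype=float)

    def select(self, year_range: tuple[int, int]) -> np.ndarray:
        y0, y1 = year_range
        m = (self.years >= y0) & (self.years <= y1)
        return self.anomaly_pct[m]


def centered_moving_average(x: np.ndarray, window: int = 7) -> np.ndarray:
    """Centred moving average (t-3 .. t+3 for the default 7-year window).

    Near the ends the window shrinks to the largest symmetric one available
    (t +/- k with k = min(half-width, distance to edge)), preserving series
    length.
    """
    x = np.asarray(x, dtype=float)
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if len(x) < window:
        raise ValueError(f"series length {len(x)} shorter than window {window}")
    h = window // 2
    out = np.empty_like(x)
    n = len(x)
    for t in range(n):
        k = min(h, t, n - 1 - t)
        out[t] = x[t - k : t + k + 1].mean()
    return out


def lowess_trend(x: np.ndarray, f: float = 0.5) -> np.ndarray:
    """LOWESS smooth of an annual series: tricube-weighted local linear
    regression over a span of ``f`` of the points, no robustifying iterations.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 10:
        raise ValueError("series too short for LOWESS trend (need >= 10)")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in series")
    t = np.arange(len(x), dtype=float)
    return _sm_lowess(x, t, frac=f, it=0, return_sorted=False)


def double_filter_detrend(
    x: np.ndarray,
    years: np.ndarray | None = None,
    window: int = 7,
    f: float = 0.5,
) -> AnomalySeries:
    """Trend = LOWESS(moving average(x)); anomalies = 100*(x - trend)/trend."""
    x = np.asarray(x, dtype=float)
    if len(x) < 15:
        raise ValueError("series too short for double-filter detrending")
    if years is None:
        years = np.arange(len(x))
    trend = lowess_trend(centered_moving_average(x, window=window), f=f)
    if np.any(trend <= 0):
        raise ValueError("nonpositive trend values: percentage anomaly undefined")
    anom = 100.0 * (x - trend) / trend
    return AnomalySeries(years=np.asarray(years), trend=trend, anomaly_pct=anom)


def iqr_of_anomalies(a: AnomalySeries, year_range: tuple[int, int]) -> float:
    """Inter-quartile range (75th - 25th percentile) of anomalies in a period."""
    vals = a.select(year_range)
    if len(vals) < 8:
        raise ValueError("need at least 8 anomaly values for an IQR")
    lo, hi = np.quantile(vals, [0.25, 0.75], method="linear")
    return float(hi - lo)


def anomaly_correlation(a1: AnomalySeries, a2: AnomalySeries) -> tuple[float, float]:
    """Pearson correlation of two anomaly series over overlapping years,
    with a two-sided t-test p-value."""
    common, i1, i2 = np.intersect1d(a1.years, a2.years, return_indices=True)
    if len(common) < 10:
        raise ValueError("need at least 10 overlapping years")
    v1 = a1.anomaly_pct[i1]
    v2 = a2.anomaly_pct[i2]
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("zero variance in an anomaly series")
    r, p = stats.pearsonr(v1, v2)
    return float(r), float(p)


def detrend_crop_series(cs: CropSeries, window: int = 7, f: float = 0.5) -> dict[str, AnomalySeries]:
    """Detrend area, yield and production of one unit, each separately."""
    return {
        "area": double_filter_detrend(cs.area, cs.years, window, f),
        "yield": double_filter_detrend(cs.yield_, cs.years, window, f),
        "production": double_filter_detrend(cs.production, cs.years, window, f),
    }


def anomalies_to_csv(unit_id: str, anomalies: dict[str, AnomalySeries], path) -> None:
    """Tidy (unit_id, year, variable, trend, anomaly_pct) CSV."""
    rows = []
    for var, a in anomalies.items():
        for yr, tr, an in zip(a.years, a.trend, a.anomaly_pct):
            rows.append((unit_id, int(yr), var, tr, an))
    pd.DataFrame(
        rows, columns=["unit_id", "year", "variable", "trend", "anomaly_pct"]
    ).to_csv(path, index=False)
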