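"""Extreme and average climate indices per crop-calendar window, and the
year x predictor matrix fed to the anomaly models.

For every season of a country's rice calendar and each of its three analysis
windows (sowing, early growing, late growing), 27 indices are computed per
census year from daily weather: 10 extreme precipitation indices and 15
extreme temperature indices following the ETCCDI definitions, plus the
window-average precipitation and temperature. With 3 windows per season this
gives 81 predictors per season, i.e. 162 columns for a two-season calendar
and 243 for a three-season calendar.

Definitions are applied strictly inside each window (no spill-over days):
a wet day has precip >= 1 mm; temperature threshold counts use strict
inequalities; WSDI/CSDI count days in runs of at least six; percentile
thresholds are empirical quantiles (linear interpolation between order
statistics) pooled over the window days of a base period. The ETCCDI in-base
bootstrap for percentile indices is deliberately not applied: thresholds are
plain pooled quantiles, which keeps them single-valued across years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calendar import PeriodWindow, SeasonCalendar, derive_periods, resolve_window_months

logger = logging.getLogger(__name__)

WET_DAY_MM = 1.0  # ETCCDI wet-day threshold

PRECIP_INDICES = (
    "RX1day", "RX5day", "SDII", "R10mm", "R20mm",
    "CDD", "CWD", "R95pTOT", "R99pTOT", "PRCPTOT", "PAVG",
)
TEMP_INDICES = (
    "TXx", "TXn", "TNx", "TNn",
    "TX10p", "TX90p", "TN10p", "TN90p",
    "FD", "SU", "ID", "TR", "WSDI", "CSDI", "DTR", "TAVG",
)
#: column order of the 27 indices inside each (season, period) block
INDEX_ORDER = PRECIP_INDICES + TEMP_INDICES
assert len(INDEX_ORDER) == 27


# ---------------------------------------------------------------------------
# Daily weather container
# ---------------------------------------------------------------------------

@dataclass
class DailyWeather:
    """Contiguous daily weather record for one location.

    tmean is derived as the arithmetic mean of tmax and tmin.
    """

    location_id: str
    dates: pd.DatetimeIndex
    tmax: np.ndarray
    tmin: np.ndarray
    precip: np.ndarray
    tmean: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.tmax = np.asarray(self.tmax, dtype=float)
        self.tmin = np.asarray(self.tmin, dtype=float)
        self.precip = np.asarray(self.precip, dtype=float)
        n = len(self.dates)
        if not (len(self.tmax) == len(self.tmin) == len(self.precip) == n):
            raise ValueError("weather arrays and dates must have equal length")
        if n == 0:
            raise ValueError("empty weather record")
        expect = pd.date_range(self.dates[0], self.dates[-1], freq="D")
        if not self.dates.equals(expect):
            raise ValueError("daily record has gaps or is unordered")
        if np.any(self.tmax < self.tmin):
            raise ValueError("tmax < tmin on some days")
        if np.any(self.precip < 0):
            raise ValueError("negative precipitation")
        self.tmean = (self.tmax + self.tmin) / 2.0
        # month index cache used by window extraction
        self._ym = self.dates.year.values * 12 + (self.dates.month.values - 1)

    @property
    def years(self) -> tuple[int, int]:
        return int(self.dates[0].year), int(self.dates[-1].year)

    def window_slice(self, window: PeriodWindow, census_year: int) -> "WindowDays":
        """Daily values inside ``window`` for one census year.

        Raises KeyError when any month of the window is not fully covered by
        the record.
        """
        months = resolve_window_months(window, census_year)
        mask = np.zeros(len(self.dates), dtype=bool)
        for (yr, mo) in months:
            ym = yr * 12 + (mo - 1)
            sel = self._ym == ym
            ndays = pd.Period(f"{yr}-{mo:02d}").days_in_month
            if sel.sum() != ndays:
                raise KeyError(
                    f"month {yr}-{mo:02d} not fully covered by weather record"
                )
            mask |= sel
        return WindowDays(
            tmax=self.tmax[mask], tmin=self.tmin[mask], precip=self.precip[mask]
        )

    @classmethod
    def from_csv(cls, path, location_id: str = "loc") -> "DailyWeather":
        """Read a (date, tmax, tmin, precip) CSV."""
        df = pd.read_csv(path, parse_dates=["date"])
        return cls(
            location_id=location_id,
            dates=pd.DatetimeIndex(df["date"]),
            tmax=df["tmax"].to_numpy(),
            tmin=df["tmin"].to_numpy(),
            precip=df["precip"].to_numpy(),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"date": self.dates, "tmax": self.tmax,
             "tmin": self.tmin, "precip": self.precip}
        ).to_csv(path, index=False)

    def to_dataset(self):
        """The record as an xarray Dataset (time dimension)."""
        import xarray as xr

        return xr.Dataset(
            {
                "tmax": ("time", self.tmax),
                "tmin": ("time", self.tmin),
                "precip": ("time", self.precip),
            },
            coords={"time": self.dates},
            attrs={"location_id": self.location_id},
        )


@dataclass(frozen=True)
class WindowDays:
    tmax: np.ndarray
    tmin: np.ndarray
    precip: np.ndarray

    def __len__(self) -> int:
        return len(self.precip)


# ---------------------------------------------------------------------------
# Percentile thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PercentileThresholds:
    """Percentile parameters for TX10p/TX90p/TN10p/TN90p and R95pTOT/R99pTOT."""

    tx10: float
    tx90: float
    tn10: float
    tn90: float
    r95: float
    r99: float
    base_period: tuple[int, int]

    def __post_init__(self) -> None:
        if not (self.tx10 <= self.tx90 and self.tn10 <= self.tn90):
            raise ValueError("temperature percentile thresholds out of order")
        if self.r95 > self.r99:
            raise ValueError("r95 must not exceed r99")


def compute_percentile_thresholds(
    w: DailyWeather,
    window: PeriodWindow,
    base_years: tuple[int, int],
    min_wet_days: int = 30,
) -> PercentileThresholds:
    """Empirical thresholds pooled over the window days of the base years.

    r95/r99 are quantiles of wet-day (>= 1 mm) precipitation only; fewer than
    ``min_wet_days`` pooled wet days raises a ValueError.
    """
    y0, y1 = base_years
    tx, tn, pr = [], [], []
    for yr in range(y0, y1 + 1):
        days = w.window_slice(window, yr)
        tx.append(days.tmax)
        tn.append(days.tmin)
        pr.append(days.precip)
    tx = np.concatenate(tx)
    tn = np.concatenate(tn)
    wet = np.concatenate(pr)
    wet = wet[wet >= WET_DAY_MM]
    if len(wet) < min_wet_days:
        raise ValueError(
            f"insufficient base sample: {len(wet)} pooled wet days "
            f"(need >= {min_wet_days}) for r95/r99"
        )
    q = lambda a, p: float(np.quantile(a, p / 100.0, method="linear"))
    return PercentileThresholds(
        tx10=q(tx, 10), tx90=q(tx, 90),
        tn10=q(tn, 10), tn90=q(tn, 90),
        r95=q(wet, 95), r99=q(wet, 99),
        base_period=(y0, y1),
    )


# ---------------------------------------------------------------------------
# Index kernels
# ---------------------------------------------------------------------------

def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def _spell_days(mask: np.ndarray, min_len: int = 6) -> int:
    """Total days belonging to runs of True of length >= min_len."""
    total = cur = 0
    for v in np.append(mask, False):
        if v:
            cur += 1
        else:
            if cur >= min_len:
                total += cur
            cur = 0
    return total


def compute_precip_index(
    name: str,
    w: DailyWeather,
    window: PeriodWindow,
    year: int,
    thr: PercentileThresholds | None = None,
) -> float:
    """One precipitation index for one window/year (ETCCDI definitions)."""
    days = w.window_slice(window, year)
    return _precip_index_from_days(name, days.precip, thr)


def _precip_index_from_days(
    name: str, p: np.ndarray, thr: PercentileThresholds | None
) -> float:
    wet = p >= WET_DAY_MM
    nwet = int(wet.sum())
    if name == "RX1day":
        return float(p.max())
    if name == "RX5day":
        if len(p) < 5:
            return float(p.sum())
        sums = np.convolve(p, np.ones(5), mode="valid")
        return float(sums.max())
    if name == "SDII":
        return float(p[wet].sum() / nwet) if nwet else 0.0
    if name == "R10mm":
        return float((p >= 10.0).sum())
    if name == "R20mm":
        return float((p >= 20.0).sum())
    if name == "CDD":
        return float(_longest_run(~wet))
    if name == "CWD":
        return float(_longest_run(wet))
    if name in ("R95pTOT", "R99pTOT"):
        if thr is None:
            raise ValueError(f"{name} requires percentile thresholds")
        cut = thr.r95 if name == "R95pTOT" else thr.r99
        return float(p[wet & (p > cut)].sum())
    if name == "PRCPTOT":
        return float(p[wet].sum())
    if name == "PAVG":
        return float(p.mean())
    raise ValueError(f"unknown precipitation index {name!r}")


def compute_temp_index(
    name: str,
    w: DailyWeather,
    window: PeriodWindow,
    year: int,
    thr: PercentileThresholds | None = None,
) -> float:
    """One temperature index for one window/year (ETCCDI definitions)."""
    days = w.window_slice(window, year)
    return _temp_index_from_days(name, days.tmax, days.tmin, thr)


def _temp_index_from_days(
    name: str, tx: np.ndarray, tn: np.ndarray, thr: PercentileThresholds | None
) -> float:
    n = len(tx)
    if name == "TXx":
        return float(tx.max())
    if name == "TXn":
        return float(tx.min())
    if name == "TNx":
        return float(tn.max())
    if name == "TNn":
        return float(tn.min())
    if name == "FD":
        return float((tn < 0.0).sum())
    if name == "SU":
        return float((tx > 25.0).sum())
    if name == "ID":
        return float((tx < 0.0).sum())
    if name == "TR":
        return float((tn > 20.0).sum())
    if name == "DTR":
        return float((tx - tn).mean())
    if name == "TAVG":
        return float(((tx + tn) / 2.0).mean())
    if thr is None:
        raise ValueError(f"{name} requires percentile thresholds")
    if name == "TX10p":
        return float(100.0 * (tx < thr.tx10).sum() / n)
    if name == "TX90p":
        return float(100.0 * (tx > thr.tx90).sum() / n)
    if name == "TN10p":
        return float(100.0 * (tn < thr.tn10).sum() / n)
    if name == "TN90p":
        return float(100.0 * (tn > thr.tn90).sum() / n)
    if name == "WSDI":
        return float(_spell_days(tx > thr.tx90))
    if name == "CSDI":
        return float(_spell_days(tn < thr.tn10))
    raise ValueError(f"unknown temperature index {name!r}")


def compute_index(
    name: str,
    w: DailyWeather,
    window: PeriodWindow,
    year: int,
    thr: PercentileThresholds | None = None,
) -> float:
    if name in PRECIP_INDICES:
        return compute_precip_index(name, w, window, year, thr)
    if name in TEMP_INDICES:
        return compute_temp_index(name, w, window, year, thr)
    raise ValueError(f"unknown index {name!r}")


# ---------------------------------------------------------------------------
# Predictor matrix
# ---------------------------------------------------------------------------

def build_predictor_matrix(
    w: DailyWeather,
    calendars: list[SeasonCalendar],
    years: range | list[int],
    base_years: tuple[int, int] | None = None,
    index_names: tuple[str, ...] = INDEX_ORDER,
) -> pd.DataFrame:
    """Assemble the year x (season, period, index) climate predictor matrix.

    Columns follow the documented order: seasons in calendar order, then the
    three periods (sowing, early_growing, late_growing), then the indices in
    ``INDEX_ORDER``. Rows are census years; years whose windows are not fully
    covered by the weather record are dropped with a warning, never imputed.

    ``base_years`` sets the percentile-threshold base period per (season,
    period) window; it defaults to the full requested year span.
    """
    years = list(years)
    if base_years is None:
        base_years = (years[0], years[-1])

    season_periods: list[tuple[SeasonCalendar, PeriodWindow]] = []
    for cal in calendars:
        for pw in derive_periods(cal):
            season_periods.append((cal, pw))

    thresholds: dict[tuple[str, str], PercentileThresholds | None] = {}
    for cal, pw in season_periods:
        try:
            thresholds[(cal.season_name, pw.period_class)] = (
                compute_percentile_thresholds(w, pw, base_years)
            )
        except KeyError:
            # base period partially outside the record: shrink to covered years
            y0 = max(base_years[0], w.years[0] + 1)
            y1 = min(base_years[1], w.years[1])
            thresholds[(cal.season_name, pw.period_class)] = (
                compute_percentile_thresholds(w, pw, (y0, y1))
            )

    columns = pd.MultiIndex.from_tuples(
        [
            (cal.season_name, pw.period_class, idx)
            for cal, pw in season_periods
            for idx in index_names
        ],
        names=["season", "period", "index"],
    )

    rows, kept_years = [], []
    for yr in years:
        try:
            row = []
            for cal, pw in season_periods:
                days = w.window_slice(pw, yr)
                thr = thresholds[(cal.season_name, pw.period_class)]
                for idx in index_names:
                    if idx in PRECIP_INDICES:
                        row.append(_precip_index_from_days(idx, days.precip, thr))
                    else:
                        row.append(_temp_index_from_days(idx, days.tmax, days.tmin, thr))
        except KeyError:
            logger.warning("year %d dropped: weather does not cover all windows", yr)
            continue
        rows.append(row)
        kept_years.append(yr)

    X = pd.DataFrame(rows, index=pd.Index(kept_years, name="year"), columns=columns)
    return X


def predictor_matrix_to_csv(X: pd.DataFrame, path) -> None:
    """Tidy CSV with a single header row encoding season|period|index."""
    flat = X.copy()
    flat.columns = [f"{s}|{p}|{i}" for s, p, i in X.columns]
    flat.to_csv(path, index_label="year")


def predictor_matrix_from_csv(path) -> pd.DataFrame:
    flat = pd.read_csv(path, index_col="year")
    flat.columns = pd.MultiIndex.from_tuples(
        [tuple(c.split("|")) for c in flat.columns],
        names=["season", "period", "index"],
    )
    return flat
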