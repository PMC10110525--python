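"""Multi-season rice cropping calendars and the analysis windows derived from them.

A country grows rice in two or three seasons per year (a wet/rainfed season
and one or two dry/irrigated seasons; in some countries two wet sub-seasons).
Each season is described by a planting month window and a harvesting month
window, both inclusive and possibly wrapping across the year boundary.

Three monthly analysis windows are derived per season:

* **sowing** — from one month before the first planting month to the last
  planting month; captures pre-planting water availability and field
  workability.
* **early_growing** — from the first planting month to the first harvesting
  month.
* **late_growing** — from the last planting month to the last harvesting
  month.

Calendars are held fixed across scenario years: observed planting/harvesting
shifts are small on a monthly grid, so the same windows are reused when
computing indices for projected climates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import yaml

SEASON_CLASSES = ("wet_rainfed", "dry_irrigated")
PERIOD_CLASSES = ("sowing", "early_growing", "late_growing")


def _wlen(first: int, last: int) -> int:
    """Inclusive length in months of a (possibly wrapping) month window."""
    return (last - first) % 12 + 1


def _check_month(m: int, what: str) -> None:
    if not (isinstance(m, int) and 1 <= m <= 12):
        raise ValueError(f"{what} must be an integer month 1-12, got {m!r}")


@dataclass(frozen=True)
class PeriodWindow:
    """An inclusive month window used to aggregate daily weather.

    ``wraps`` is True when the window crosses December into January.
    ``months_before_anchor`` positions the window on the season's unwrapped
    time axis: it is the number of months from this window's last month to
    the season's harvest-end month (the anchor attributed to the census
    year), and lets wrapped or previous-year windows resolve to concrete
    (year, month) pairs.
    """

    period_class: str
    first_month: int
    last_month: int
    wraps: bool
    months_before_anchor: int = 0

    def __post_init__(self) -> None:
        if self.period_class not in PERIOD_CLASSES:
            raise ValueError(f"unknown period class {self.period_class!r}")
        _check_month(self.first_month, "first_month")
        _check_month(self.last_month, "last_month")
        if not 2 <= self.length <= 12:
            raise ValueError(
                f"{self.period_class} window {self.first_month}-{self.last_month} "
                f"has length {self.length}; must be 2-12 months"
            )
        if self.wraps != (self.first_month > self.last_month):
            raise ValueError("wrap flag inconsistent with month window")

    @property
    def length(self) -> int:
        return _wlen(self.first_month, self.last_month)

    def months(self) -> list[int]:
        """The calendar months covered, in temporal order."""
        return [(self.first_month - 1 + k) % 12 + 1 for k in range(self.length)]


@dataclass(frozen=True)
class SeasonCalendar:
    """One rice season: class, planting and harvesting month windows.

    ``census_year_rule`` states which calendar year a harvest is attributed
    to; the default attributes the season to the year containing the last
    harvesting month, which is unambiguous and monotone for seasons that wrap
    the year end.
    """

    season_name: str
    season_class: str
    planting_window: tuple[int, int]
    harvesting_window: tuple[int, int]
    census_year_rule: str = "harvest_end_year"

    def __post_init__(self) -> None:
        if self.season_class not in SEASON_CLASSES:
            raise ValueError(f"unknown season class {self.season_class!r}")
        for m, what in (
            (self.planting_window[0], "planting first month"),
            (self.planting_window[1], "planting last month"),
            (self.harvesting_window[0], "harvesting first month"),
            (self.harvesting_window[1], "harvesting last month"),
        ):
            _check_month(m, what)
        if self.census_year_rule != "harvest_end_year":
            raise ValueError(f"unsupported census_year_rule {self.census_year_rule!r}")
        # unwrap the season onto a single time axis and reject degenerate spans
        offs = self._unwrapped_offsets()
        if offs["harvest_last"] + 1 > 12:
            raise ValueError(
                f"season {self.season_name!r}: planting-to-harvest span exceeds 12 months"
            )
        if offs["harvest_last"] <= 0:
            raise ValueError(
                f"season {self.season_name!r}: planting must precede harvesting"
            )

    def _unwrapped_offsets(self) -> dict[str, int]:
        """Month offsets of the four window bounds on the season's time axis.

        Offset 0 is the first planting month; later months have larger
        offsets, unwrapping across the year boundary where needed.
        """
        p1, p2 = self.planting_window
        h1, h2 = self.harvesting_window
        o_p2 = (p2 - p1) % 12
        o_h1 = o_p2 + (h1 - p2) % 12
        o_h2 = o_h1 + (h2 - h1) % 12
        return {
            "plant_first": 0,
            "plant_last": o_p2,
            "harvest_first": o_h1,
            "harvest_last": o_h2,
        }


def derive_periods(cal: SeasonCalendar) -> tuple[PeriodWindow, PeriodWindow, PeriodWindow]:
    """Derive the sowing, early-growing and late-growing windows of a season.

    Rules (months inclusive, windows may wrap December into January):

    * sowing: one month before the first planting month .. last planting month
    * early_growing: first planting month .. first harvesting month
    * late_growing: last planting month .. last harvesting month
    """
    p1, p2 = cal.planting_window
    h1, h2 = cal.harvesting_window
    offs = cal._unwrapped_offsets()
    anchor = offs["harvest_last"]

    def mk(period_class: str, first: int, last: int, last_offset: int) -> PeriodWindow:
        return PeriodWindow(
            period_class=period_class,
            first_month=first,
            last_month=last,
            wraps=first > last,
            months_before_anchor=anchor - last_offset,
        )

    sowing_first = (p1 - 2) % 12 + 1  # one month before planting, mod 12
    return (
        mk("sowing", sowing_first, p2, offs["plant_last"]),
        mk("early_growing", p1, h1, offs["harvest_first"]),
        mk("late_growing", p2, h2, offs["harvest_last"]),
    )


def resolve_window_months(window: PeriodWindow, census_year: int) -> list[tuple[int, int]]:
    """Concrete (year, month) pairs covered by ``window`` for one census year.

    The window's last month lies ``months_before_anchor`` months before the
    season's harvest-end month, which itself sits in ``census_year``.
    """
    # anchor month = window's last month advanced by months_before_anchor
    anchor_month = (window.last_month - 1 + window.months_before_anchor) % 12 + 1
    anchor_abs = census_year * 12 + (anchor_month - 1)
    last_abs = anchor_abs - window.months_before_anchor
    out = []
    for k in range(window.length - 1, -1, -1):
        a = last_abs - k
        out.append((a // 12, a % 12 + 1))
    return out


# ---------------------------------------------------------------------------
# Calendar configuration files
# ---------------------------------------------------------------------------

def load_calendar_config(path: str | Path) -> dict[str, list[SeasonCalendar]]:
    """Read a YAML/JSON calendar config: country -> list of seasons.

    Schema per season::

        name: wet
        class: wet_rainfed
        planting: [5, 6]      # first, last month
        harvesting: [9, 10]
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return parse_calendar_config(raw)


def parse_calendar_config(raw: dict) -> dict[str, list[SeasonCalendar]]:
    out: dict[str, list[SeasonCalendar]] = {}
    for country, seasons in raw.items():
        cals = [
            SeasonCalendar(
                season_name=s["name"],
                season_class=s["class"],
                planting_window=tuple(s["planting"]),
                harvesting_window=tuple(s["harvesting"]),
                census_year_rule=s.get("census_year_rule", "harvest_end_year"),
            )
            for s in seasons
        ]
        if not 2 <= len(cals) <= 3:
            raise ValueError(
                f"{country}: expected 2 or 3 seasons, got {len(cals)}"
            )
        out[country] = cals
    return out


def example_calendars(n_seasons: int = 2) -> list[SeasonCalendar]:
    """Packaged example calendars for a two- or three-season country.

    The two-season calendar mimics a monsoon country with a wet/rainfed main
    season and a dry/irrigated season wrapping the year end; the three-season
    variant adds a second, earlier wet sub-season.
    """
    wet = SeasonCalendar("wet", "wet_rainfed", (5, 6), (9, 10))
    dry = SeasonCalendar("dry", "dry_irrigated", (11, 12), (3, 4))
    if n_seasons == 2:
        return [wet, dry]
    if n_seasons == 3:
        early_wet = SeasonCalendar("wet_early", "wet_rainfed", (3, 4), (7, 8))
        return [early_wet, wet, dry]
    raise ValueError("n_seasons must be 2 or 3")
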