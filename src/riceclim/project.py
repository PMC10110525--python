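"""Scenario projection: reliability masking, decadal trend tests, and
combination of area and yield changes into production changes.

Empirical anomaly models can produce unrealistically large responses when a
scenario year's climate predictors fall outside the ranges seen in
training. Each projected year therefore carries a reliability ratio — the
fraction of its 162-243 predictors lying inside the observed per-column
min-max ranges (one pooled reference range set per unit; ranges are nearly
identical across training subsets, so per-model ranges are not used). Years
with ratio < 0.90 are excluded before fitting a decadal trend (OLS slope of
anomaly on year, x10 for % per decade, two-sided t-test); a trend is "not
testable" when fewer than ``min_n`` reliable years remain.

Production anomalies combine area and yield multiplicatively:
100*((1 + a/100)(1 + y/100) - 1), which reduces to a + y for small
anomalies but keeps the two components' signs able to offset each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ProjectionRecord:
    """One unit-year projected anomaly with its reliability ratio."""

    unit_id: str
    response: str
    scenario: str
    year: int
    anomaly_pct: float
    reliability_ratio: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.reliability_ratio <= 1.0:
            raise ValueError("reliability ratio must lie in [0, 1]")


@dataclass
class TrendResult:
    """Decadal trend of projected anomalies over the reliable years."""

    slope_per_decade: float | None
    p_value: float | None
    n_reliable: int
    significant: bool
    testable: bool


def predictor_ranges(X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Pooled per-column min-max over the full observed predictor record."""
    A = np.asarray(X, dtype=float)
    return A.min(axis=0), A.max(axis=0)


def reliability_ratio(
    x_row: np.ndarray, col_min: np.ndarray, col_max: np.ndarray
) -> float:
    """Fraction of predictors inside the observed min-max ranges (inclusive)."""
    x = np.asarray(x_row, dtype=float).ravel()
    if not (len(x) == len(col_min) == len(col_max)):
        raise ValueError("predictor row and range schema mismatch")
    inside = (x >= col_min) & (x <= col_max)
    return float(inside.sum() / len(x))


def project_anomalies(
    fits,
    X_scenario: pd.DataFrame,
    col_min: np.ndarray,
    col_max: np.ndarray,
    unit_id: str = "unit",
    response: str = "area",
    scenario: str = "scenario",
) -> list[ProjectionRecord]:
    """Apply an ensemble of fits to scenario predictors.

    The projected anomaly for a year is the median over all models; its
    reliability ratio is computed once per year against the pooled observed
    ranges, independent of the training subsets.
    """
    records = []
    for j, year in enumerate(X_scenario.index):
        row = X_scenario.iloc[[j]]
        members = np.array([float(f.predict(row)[0]) for f in fits])
        ratio = reliability_ratio(row.to_numpy(), col_min, col_max)
        records.append(
            ProjectionRecord(
                unit_id=unit_id,
                response=response,
                scenario=scenario,
                year=int(year),
                anomaly_pct=float(np.median(members)),
                reliability_ratio=ratio,
            )
        )
    return records


def filter_reliable(
    records: list[ProjectionRecord], threshold: float = 0.90
) -> list[ProjectionRecord]:
    """Keep projections whose ratio is at least the threshold (inclusive)."""
    return [r for r in records if r.reliability_ratio >= threshold]


def decadal_trend_test(
    retained: list[ProjectionRecord],
    alpha: float = 0.05,
    min_n: int = 10,
) -> TrendResult:
    """OLS slope of anomaly on year (x10 = % per decade), two-sided t-test.

    Fewer than ``min_n`` reliable years make the trend not testable; a
    degenerate (constant-year) sample likewise.
    """
    n = len(retained)
    if n < min_n:
        return TrendResult(None, None, n, significant=False, testable=False)
    years = np.array([r.year for r in retained], dtype=float)
    anoms = np.array([r.anomaly_pct for r in retained], dtype=float)
    if np.std(years) == 0:
        return TrendResult(None, None, n, significant=False, testable=False)
    res = stats.linregress(years, anoms)
    slope_dec = float(res.slope * 10.0)
    p = float(res.pvalue)
    if np.std(anoms - res.slope * years) == 0 and res.slope != 0:
        p = 0.0  # exact line: no residual variance, slope certain
    return TrendResult(
        slope_per_decade=slope_dec,
        p_value=p,
        n_reliable=n,
        significant=bool(p < alpha),
        testable=True,
    )


def combine_production(area_anomaly_pct, yield_anomaly_pct):
    """Production anomaly implied by simultaneous area and yield anomalies.

    Multiplicative in relative terms: 100*((1 + a/100)(1 + y/100) - 1).
    """
    a = np.asarray(area_anomaly_pct, dtype=float)
    y = np.asarray(yield_anomaly_pct, dtype=float)
    if np.any(a <= -100) or np.any(y <= -100):
        raise ValueError("anomaly <= -100% has no multiplicative meaning")
    out = 100.0 * ((1.0 + a / 100.0) * (1.0 + y / 100.0) - 1.0)
    return float(out) if out.ndim == 0 else out


def combine_production_records(
    area: list[ProjectionRecord], yld: list[ProjectionRecord]
) -> list[ProjectionRecord]:
    """Year-matched production projections from area and yield projections.

    The production reliability ratio is the minimum of the two components'
    ratios (a production figure is only as reliable as its least reliable
    input).
    """
    ymap = {r.year: r for r in yld}
    out = []
    for ra in area:
        if ra.year not in ymap:
            continue
        ry = ymap[ra.year]
        out.append(
            ProjectionRecord(
                unit_id=ra.unit_id,
                response="production",
                scenario=ra.scenario,
                year=ra.year,
                anomaly_pct=combine_production(ra.anomaly_pct, ry.anomaly_pct),
                reliability_ratio=min(ra.reliability_ratio, ry.reliability_ratio),
            )
        )
    return out


def area_weighted_change(
    delta_t: np.ndarray, delta_p: np.ndarray, weights: np.ndarray
) -> tuple[float, float]:
    """Area-weighted mean temperature (degC) and precipitation (%) changes
    over a region, using a fixed crop-area map as the weights; zero-weight
    cells are ignored."""
    dt = np.asarray(delta_t, dtype=float)
    dp = np.asarray(delta_p, dtype=float)
    ww = np.asarray(weights, dtype=float)
    if not (dt.shape == dp.shape == ww.shape):
        raise ValueError("misaligned grids")
    if np.any(ww < 0):
        raise ValueError("negative weights")
    tot = ww.sum()
    if tot == 0:
        raise ValueError("all weights are zero")
    return float((dt * ww).sum() / tot), float((dp * ww).sum() / tot)


def projections_to_csv(records: list[ProjectionRecord], path, threshold: float = 0.90) -> None:
    pd.DataFrame(
        [
            {"unit_id": r.unit_id, "scenario": r.scenario, "year": r.year,
             "response": r.response, "anomaly_pct": r.anomaly_pct,
             "reliability_ratio": r.reliability_ratio,
             "retained": r.reliability_ratio >= threshold}
            for r in records
        ]
    ).to_csv(path, index=False)


def trend_report_row(country: str, scenario: str, response: str, tr: TrendResult) -> dict:
    return {
        "country": country,
        "scenario": scenario,
        "response": response,
        "slope_per_decade": tr.slope_per_decade,
        "p_value": tr.p_value,
        "n_reliable": tr.n_reliable,
        "significant": tr.significant,
        "testable": tr.testable,
    }
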