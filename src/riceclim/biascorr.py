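"""Empirical-CDF quantile-mapping bias correction of scenario daily weather.

For each variable and location the distributional error of a climate-model
series relative to a reference is tabulated percentile by percentile over a
training period: at each percentile of the two empirical CDFs the error is
the model quantile minus the reference quantile (temperatures, additive) or
the model/reference quantile ratio (precipitation, multiplicative). The
correction removes that error from any target-period model value at the
percentile the value occupies in the model training CDF, assuming the
error-percentile relationship is stationary in time.

The multiplicative form for precipitation preserves zeros and
non-negativity; the map is fitted on wet days (>= 0.1 mm) and dry days pass
through unchanged. Between grid percentiles the error is linearly
interpolated; beyond the 1st/99th percentile it is held flat, avoiding
extrapolation into unseen extremes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VARIABLES = ("tmax", "tmin", "precip")
PRECIP_FIT_WET_MM = 0.1  # wet-day cut used when fitting the precipitation map


@dataclass
class QuantileMap:
    """Percentile-indexed error table for one variable at one location.

    ``errors[i]`` is the model-train minus reference-train quantile
    (additive) or their ratio (multiplicative) at ``percentiles[i]``;
    ``model_quantiles`` are the model-train quantiles at the same grid, used
    to place a target value on the percentile axis.
    """

    variable: str
    percentiles: np.ndarray
    errors: np.ndarray
    model_quantiles: np.ndarray
    form: str = field(default="additive")

    def __post_init__(self) -> None:
        self.percentiles = np.asarray(self.percentiles, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        self.model_quantiles = np.asarray(self.model_quantiles, dtype=float)
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        if self.form not in ("additive", "multiplicative"):
            raise ValueError(f"unknown transfer form {self.form!r}")
        if np.any(np.diff(self.percentiles) <= 0):
            raise ValueError("percentile grid must be strictly increasing")
        if self.form == "multiplicative" and np.any(self.errors < 0):
            raise ValueError("multiplicative correction ratios must be >= 0")


def fit_quantile_map(
    model_train: np.ndarray,
    ref_train: np.ndarray,
    variable: str,
    percentiles: np.ndarray | None = None,
    form: str | None = None,
) -> QuantileMap:
    """Tabulate the model-vs-reference quantile error on a percentile grid.

    ``form`` defaults to additive for temperatures and multiplicative for
    precipitation; both forms are selectable for any variable.
    """
    model_train = np.asarray(model_train, dtype=float)
    ref_train = np.asarray(ref_train, dtype=float)
    if len(model_train) < 100 or len(ref_train) < 100:
        raise ValueError("need >= 100 training values in both samples")
    if percentiles is None:
        percentiles = np.arange(1.0, 100.0)
    if form is None:
        form = "multiplicative" if variable == "precip" else "additive"

    if variable == "precip":
        model_fit = model_train[model_train >= PRECIP_FIT_WET_MM]
        ref_fit = ref_train[ref_train >= PRECIP_FIT_WET_MM]
        if len(model_fit) == 0 or len(ref_fit) == 0:
            raise ValueError("zero wet days in a precipitation training sample")
    else:
        model_fit, ref_fit = model_train, ref_train

    qm = np.quantile(model_fit, np.asarray(percentiles) / 100.0, method="linear")
    qr = np.quantile(ref_fit, np.asarray(percentiles) / 100.0, method="linear")
    if form == "additive":
        err = qm - qr
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            err = np.where(qr > 0, qm / qr, 1.0)
    return QuantileMap(
        variable=variable,
        percentiles=np.asarray(percentiles, dtype=float),
        errors=err,
        model_quantiles=qm,
        form=form,
    )


def apply_quantile_map(qm: QuantileMap, model_target: np.ndarray) -> np.ndarray:
    """Remove the tabulated error from a target-period model series.

    Each value is placed at its percentile in the model training CDF (linear
    interpolation between grid quantiles, flat beyond), the error at that
    percentile is interpolated, and subtracted (additive) or divided out
    (multiplicative). The map is monotone, so value order is preserved.
    """
    x = np.asarray(model_target, dtype=float)
    out = x.copy()
    if qm.variable == "precip":
        active = x >= PRECIP_FIT_WET_MM  # dry days pass through unchanged
    else:
        active = np.ones_like(x, dtype=bool)
    if not np.any(active):
        return out

    xa = x[active]
    # percentile of each value in the model-train CDF; flat beyond the grid
    pct = np.interp(xa, qm.model_quantiles, qm.percentiles)
    err = np.interp(pct, qm.percentiles, qm.errors)
    if qm.form == "additive":
        corrected = xa - err
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            corrected = np.where(err > 0, xa / err, xa)
        corrected = np.maximum(corrected, 0.0)
    out[active] = corrected
    return out


def bias_correct_weather(weather, reference, train_slice=None):
    """Correct a DailyWeather record against a reference record.

    ``train_slice`` is a boolean mask (or None for the full overlap) marking
    the training days in both records; all three variables are corrected
    with their default transfer forms. Returns a new DailyWeather.
    """
    from .indices import DailyWeather

    if train_slice is None:
        train_slice = np.ones(len(weather.dates), dtype=bool)
    corrected = {}
    for var in VARIABLES:
        mt = getattr(weather, var)[train_slice]
        rt = getattr(reference, var)[train_slice]
        qmap = fit_quantile_map(mt, rt, var)
        corrected[var] = apply_quantile_map(qmap, getattr(weather, var))
    # corrected tmax/tmin may cross on rare days; restore the ordering
    tmax = np.maximum(corrected["tmax"], corrected["tmin"])
    tmin = np.minimum(corrected["tmax"], corrected["tmin"])
    return DailyWeather(
        location_id=weather.location_id,
        dates=weather.dates,
        tmax=tmax,
        tmin=tmin,
        precip=corrected["precip"],
    )
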