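"""Elastic-net anomaly models under a rolling forecasting origin.

Annual area (or yield) anomalies of one administrative unit are regressed on
the 162-243 climate predictors with elastic-net regularization, which
tolerates p >> n and correlated predictors. Models are trained on 25
consecutive years and predict later years only (rolling forecasting origin):
a 52-year record yields 27 models, the first trained on years 1-25
predicting year 26, the last trained on years 27-51 predicting year 52. Each
target year's ensemble members are all models whose training window precedes
it, and the member median is the prediction used downstream; a strict
one-step-ahead mode (each year predicted only by the model whose origin it
is) is available as an alternative.

Predictors are standardized on each training subset; coefficients are
reported on the standardized scale so they are comparable across predictors,
units and training subsets, and are averaged to characterize country-scale
climate influences. Each fit also records per-column training min-max
ranges, consumed by projection reliability scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

#: elastic-net mixing grid searched by internal cross-validation
L1_RATIO_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))


@dataclass
class ModelFit:
    """One elastic-net fit on 25 training years, standardized scale."""

    unit_id: str
    response: str
    training_years: np.ndarray
    columns: list[tuple]
    coef: np.ndarray            # standardized-scale coefficients, zeros allowed
    intercept: float
    l1_ratio: float
    alpha: float
    col_mean: np.ndarray
    col_sd: np.ndarray          # zero-variance columns keep sd recorded as 0
    col_min: np.ndarray         # raw-scale training min per column
    col_max: np.ndarray
    degenerate: bool = False    # zero-variance response flag
    dropped_columns: list[int] = field(default_factory=list)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predict anomalies for new predictor rows (raw scale in, % out)."""
        Z = standardize_like(self, X)
        return Z @ self.coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "unit_id": self.unit_id,
            "response": self.response,
            "training_years": self.training_years.tolist(),
            "columns": [list(c) for c in self.columns],
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "l1_ratio": self.l1_ratio,
            "alpha": self.alpha,
            "col_mean": self.col_mean.tolist(),
            "col_sd": self.col_sd.tolist(),
            "col_min": self.col_min.tolist(),
            "col_max": self.col_max.tolist(),
            "degenerate": self.degenerate,
            "dropped_columns": self.dropped_columns,
        }


def standardize_like(fit: ModelFit, X: pd.DataFrame) -> np.ndarray:
    """Standardize predictor rows with a fit's training mean/sd; columns with
    zero training variance map to 0 (their coefficient is 0 by convention)."""
    A = np.asarray(X, dtype=float)
    sd = np.where(fit.col_sd > 0, fit.col_sd, 1.0)
    Z = (A - fit.col_mean) / sd
    Z[:, fit.col_sd == 0] = 0.0
    return Z


def fit_elastic_net(
    X: pd.DataFrame,
    y: np.ndarray,
    unit_id: str = "unit",
    response: str = "area",
    seed: int = 0,
    cv_folds: int = 5,
    n_alphas: int = 50,
    l1_ratios: tuple[float, ...] = L1_RATIO_GRID,
) -> ModelFit:
    """Fit one elastic net with internal CV over mixing and penalty strength.

    Predictors are standardized on the training subset; zero-variance
    columns are dropped from the optimisation and reported with coefficient
    0. A zero-variance response short-circuits to the all-zero model with
    intercept mean(y), flagged ``degenerate``.
    """
    y = np.asarray(y, dtype=float)
    A = np.asarray(X, dtype=float)
    if np.any(~np.isfinite(A)) or np.any(~np.isfinite(y)):
        raise ValueError("missing or non-finite cells in training data")
    years = np.asarray(X.index, dtype=int)
    cols = list(X.columns)
    mean = A.mean(axis=0)
    sd = A.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = list(np.where(~keep)[0])
    base = dict(
        unit_id=unit_id,
        response=response,
        training_years=years,
        columns=cols,
        col_mean=mean,
        col_sd=np.where(keep, sd, 0.0),
        col_min=A.min(axis=0),
        col_max=A.max(axis=0),
        dropped_columns=dropped,
    )
    if np.std(y) == 0:
        return ModelFit(
            coef=np.zeros(A.shape[1]),
            intercept=float(y.mean()),
            l1_ratio=np.nan,
            alpha=np.nan,
            degenerate=True,
            **base,
        )
    Z = (A[:, keep] - mean[keep]) / sd[keep]
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    enet = ElasticNetCV(
        l1_ratio=list(l1_ratios),
        alphas=n_alphas,  # length of the auto-scaled penalty path
        cv=cv,
        max_iter=20000,
        random_state=seed,
    )
    enet.fit(Z, y)
    coef = np.zeros(A.shape[1])
    coef[keep] = enet.coef_
    return ModelFit(
        coef=coef,
        intercept=float(enet.intercept_),
        l1_ratio=float(enet.l1_ratio_),
        alpha=float(enet.alpha_),
        **base,
    )


@dataclass
class EnsemblePrediction:
    """Member and median predictions for one target year."""

    unit_id: str
    response: str
    year: int
    members: np.ndarray
    median: float

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=float)
        assert np.isclose(self.median, np.median(self.members))


def rolling_origin_ensemble(
    X: pd.DataFrame,
    y: np.ndarray,
    train_len: int = 25,
    seed: int = 0,
    unit_id: str = "unit",
    response: str = "area",
    mode: str = "ensemble",
    **fit_kwargs,
) -> tuple[list[ModelFit], list[EnsemblePrediction]]:
    """Rolling forecasting origin: one model per origin, ensemble per year.

    For each origin t (index ``train_len`` .. n-1) a model is trained on the
    ``train_len`` years t-train_len .. t-1. In ``ensemble`` mode the members
    for a target year are all models whose training window ends before it
    (so the year is out of sample for every member) and the median is taken;
    ``one_step`` mode keeps only each origin's own one-step-ahead forecast.
    """
    if mode not in ("ensemble", "one_step"):
        raise ValueError(f"unknown mode {mode!r}")
    y = np.asarray(y, dtype=float)
    years = np.asarray(X.index, dtype=int)
    n = len(years)
    if n < train_len + 1:
        raise ValueError(
            f"record length {n} must exceed training length {train_len}"
        )
    fits: list[ModelFit] = []
    for origin in range(train_len, n):
        Xi = X.iloc[origin - train_len : origin]
        yi = y[origin - train_len : origin]
        fits.append(
            fit_elastic_net(
                Xi, yi, unit_id=unit_id, response=response, seed=seed, **fit_kwargs
            )
        )

    preds: list[EnsemblePrediction] = []
    for j in range(train_len, n):
        row = X.iloc[[j]]
        if mode == "ensemble":
            # origin index of fit k is train_len + k; members are all models
            # whose training window ends before the target year
            member_fits = fits[: j - train_len + 1]
        else:
            member_fits = [fits[j - train_len]]
        members = np.array([float(f.predict(row)[0]) for f in member_fits])
        preds.append(
            EnsemblePrediction(
                unit_id=unit_id,
                response=response,
                year=int(years[j]),
                members=members,
                median=float(np.median(members)),
            )
        )
    return fits, preds


@dataclass
class ValidationMetrics:
    R: float
    p_value: float
    rmse: float
    n: int


def validation_metrics(preds: list[EnsemblePrediction], obs, years=None) -> ValidationMetrics:
    """Out-of-sample skill: Pearson R (two-sided test) and RMSE in % points.

    ``obs`` is an AnomalySeries; ``years`` optionally restricts the
    comparison period.
    """
    pred_map = {p.year: p.median for p in preds}
    obs_map = dict(zip(obs.years.tolist(), obs.anomaly_pct.tolist()))
    common = sorted(set(pred_map) & set(obs_map))
    if years is not None:
        common = [y for y in common if years[0] <= y <= years[-1]]
    if len(common) < 3:
        raise ValueError("need at least 3 overlapping years")
    p = np.array([pred_map[y] for y in common])
    o = np.array([obs_map[y] for y in common])
    if np.std(o) == 0 or np.std(p) == 0:
        raise ValueError("zero variance in predictions or observations")
    r, pv = stats.pearsonr(p, o)
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    return ValidationMetrics(R=float(r), p_value=float(pv), rmse=rmse, n=len(common))


def aggregate_country_coefficients(fits: list[ModelFit]) -> pd.Series:
    """Unweighted mean standardized coefficient per predictor across all
    units and training subsets of one country/response."""
    if not fits:
        raise ValueError("no fits to aggregate")
    cols = fits[0].columns
    for f in fits:
        if f.columns != cols:
            raise ValueError("column schema mismatch across fits")
    M = np.vstack([f.coef for f in fits])
    idx = (pd.MultiIndex.from_tuples(cols, names=["season", "period", "index"])
           if isinstance(cols[0], tuple) else pd.Index(cols))
    return pd.Series(M.mean(axis=0), index=idx)


def top_contributors(avg_coef: pd.Series, sign: str, k: int = 3) -> list[tuple]:
    """The k largest positive (or most negative) averaged coefficients.

    Ties are broken by column order; fewer than k nonzero coefficients of
    the requested sign return a shorter list.
    """
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    vals = avg_coef.values
    order = np.arange(len(vals))
    if sign == "positive":
        cand = [(i, vals[i]) for i in order if vals[i] > 0]
        cand.sort(key=lambda t: (-t[1], t[0]))
    else:
        cand = [(i, vals[i]) for i in order if vals[i] < 0]
        cand.sort(key=lambda t: (t[1], t[0]))
    return [avg_coef.index[i] for i, _ in cand[:k]]


def pick_representative_cell(weights) -> tuple:
    """Grid cell carrying the largest rice area for a unit (ties: lowest id).

    ``weights`` maps cell id -> area weight, or is a 2-D array whose (row,
    col) indices serve as ids.
    """
    if isinstance(weights, np.ndarray):
        if weights.ndim != 2:
            raise ValueError("array weights must be 2-D")
        items = [((i, j), weights[i, j])
                 for i in range(weights.shape[0])
                 for j in range(weights.shape[1])]
    else:
        items = sorted(weights.items())
    if all(v <= 0 for _, v in items):
        raise ValueError("all cell weights are zero")
    best = max(items, key=lambda t: t[1])  # max is stable: first wins ties
    return best[0]


def fits_to_json(fits: list[ModelFit], path) -> None:
    with open(path, "w") as fh:
        json.dump([f.to_dict() for f in fits], fh)


def predictions_to_csv(preds: list[EnsemblePrediction], path) -> None:
    pd.DataFrame(
        [
            {"unit_id": p.unit_id, "response": p.response, "year": p.year,
             "n_members": len(p.members), "median_anomaly_pct": p.median}
            for p in preds
        ]
    ).to_csv(path, index=False)
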