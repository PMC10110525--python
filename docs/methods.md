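# Methods

This note documents the statistical model, the numerical conventions, the
synthetic study design, and the choices made where the design was genuinely
open.

## Crop calendars and analysis windows

A season is a (planting window, harvesting window) pair of inclusive month
ranges, either of which may wrap December→January. Three analysis windows
are derived per season: **sowing** (one month before the first planting
month through the last planting month), **early growing** (first planting
month through first harvesting month) and **late growing** (last planting
month through last harvesting month). The sowing window exists because
pre-planting climate plausibly affects *planted area* (water availability,
field workability) while barely affecting yield — it is the one month that
separates sowing from early growing.

**Census-year anchoring.** A season is attributed to the calendar year
containing its *last harvesting month* (unambiguous and monotone for
wrapped seasons). Every window month is then counted back from that anchor
on the season's unwrapped time axis. This generalises the obvious
Dec(y−1)/Jan(y) split: for a season planted Nov–Dec and harvested Mar–Apr,
the whole sowing window (Oct–Dec) falls in year y−1 even though it does not
itself wrap. Seasons whose planting-to-harvest span unwraps to more than 12
months are rejected. Calendars are held fixed across scenario years;
observed planting-date shifts are small relative to a monthly grid.

## Climate indices

27 indices per (season, window, year): 10 ETCCDI precipitation extremes,
15 ETCCDI temperature extremes, and window-average precipitation (PAVG,
mm/day) and temperature (TAVG, °C). Conventions, all inside the window only:

- wet day: precip ≥ 1 mm; dry otherwise. CDD/CWD are the longest dry/wet
  runs; runs do not extend across window boundaries.
- RX5day uses 5-day sums fully inside the window; SDII = PRCPTOT / wet-day
  count, 0 when the window is entirely dry.
- R95pTOT/R99pTOT sum precipitation of wet days strictly above the
  95th/99th percentile of pooled wet-day amounts from a base period.
- Threshold counts (FD tmin<0 °C, SU tmax>25 °C, ID tmax<0 °C, TR
  tmin>20 °C, TX10p/TX90p/TN10p/TN90p) use strict inequalities; the
  percentile counts are expressed as % of window days. WSDI/CSDI count days
  in runs of ≥ 6 days with tmax > tx90 / tmin < tn10.
- The 15-index temperature set is the standard ETCCDI list minus GSL
  (growing-season length is an annual index, meaningless in sub-annual
  windows); the index list is configurable at the API level.
- Percentile thresholds are plain empirical quantiles (linear interpolation
  between order statistics) pooled over the window days of a configurable
  base period (default: the full analysed span). The ETCCDI in-base
  bootstrap for percentile indices is deliberately omitted; its purpose is
  to remove a small inhomogeneity between in-base and out-of-base years,
  which is immaterial here because thresholds feed predictors, not
  homogeneity-sensitive trend statistics. Fewer than 30 pooled wet days is
  an error rather than a silently unstable r95/r99.

The predictor matrix orders columns (season, period, index), seasons in
calendar order, periods sowing → early growing → late growing. Years whose
windows are not fully covered by the weather record are dropped with a
warning, never imputed.

## Detrending

Trend = LOWESS(MA₇(x)) with a centred 7-year moving average and LOWESS span
f = 0.5 (fraction of points, the standard reading), local linear, zero
robustifying iterations — matching the common default of the R
implementation the procedure originates from. Anomaly = 100·(x − trend)/trend.
Area, yield and production are each detrended separately; production
anomalies come from detrending area × yield itself.

Edge handling for the moving average (otherwise an open choice): the window
shrinks to the largest *symmetric* window available (t ± k,
k = min(3, distance to edge)), preserving series length for the 52-year
bookkeeping downstream. Nonpositive trend values are an error (percentage
anomalies undefined).

Two quantified caveats, both visible in the tests: (i) a serially
uncorrelated climate signal leaks ~1/7 of its variance into the 7-year
moving average, capping the correlation between the true signal and the
detrended anomaly near √(6/7) ≈ 0.96 — detrending can never be perfectly
signal-preserving at these filter scales; (ii) the double filter is only
approximately idempotent: re-detrending its own trend output leaves
residual anomalies an order of magnitude smaller than the data's.

## Bias correction

Empirical-CDF quantile mapping per variable: the model-minus-reference
quantile error is tabulated on a 1–99 percentile grid over a training
period, linearly interpolated in percentile, held flat beyond the grid
(no extrapolation into unseen extremes), and removed from target values at
the percentile each value occupies in the model-train CDF. The transfer
form is additive for temperatures and multiplicative for precipitation —
the multiplicative form preserves zeros and non-negativity; both forms are
selectable. The precipitation map is fitted on wet days (≥ 0.1 mm); dry
days pass through unchanged. The map is monotone by construction, so value
ordering is preserved.

## Anomaly models

Elastic net (L1/L2 blend) of anomalies on the predictor matrix, per unit
and response. Predictors are standardized on each 25-year training subset;
coefficients are reported on the standardized scale. Hyperparameters —
mixing parameter over {0.1, …, 1.0} and a 50-point auto-scaled penalty
path — are chosen by 5-fold cross-validation with a fixed seed. Columns
with zero training variance are dropped from the fit and reported with
coefficient 0. A zero-variance response short-circuits to the null model,
flagged.

**Rolling forecasting origin.** One model per origin t, trained on years
t−25 … t−1. With 52 years this gives 27 models (origins 1986–2012). Two
documented readings of the ensemble exist; we implement the one that makes
a "median of 27 predictions" well defined: every origin model predicts
every *subsequent* year (for which it is out of sample by construction) and
the per-year median is taken over all such members — 1 member for the first
validation year growing to 27 for the last. A strict one-step-ahead mode
(each year predicted only by its own origin model) is available as a
configuration alternative. Validation metrics (Pearson R with two-sided
test, RMSE in percentage points) compare the median series with observed
anomalies over the validation years.

Country-scale climate influences are the unweighted arithmetic mean of
standardized coefficients across units × training subsets; top contributors
are the k largest positive / most negative averaged coefficients, ties
broken by column order. For gridded weather a unit's representative cell is
the one with the largest rice-area weight (ties: lowest index).

## Projection and reliability

The reliability ratio of a projected year is the fraction of its predictors
inside the observed per-column min–max ranges, bounds inclusive. One pooled
reference range set (full observed record) is used per unit rather than
per-training-subset ranges, which are nearly identical; this gives a single
well-defined mask. Years with ratio < 0.90 are excluded; the decadal trend
is OLS of anomaly on year (slope × 10 = % per decade) with a two-sided
t-test at α = 0.05, not testable below 10 reliable years (both
configurable). Production combines area and yield multiplicatively,
100·((1+a/100)(1+y/100) − 1), reducing to a + y within 0.25 points when
|a|,|y| ≤ 5; a production record's reliability is the minimum of its two
components'. Area-weighted regional ΔT/ΔP are weighted means over a fixed
crop-area map. Trends are fitted on country-aggregated series (the
alternative — aggregating unit-level trends — is not implemented).

## Synthetic study design

The weather generator emulates a ~52-year monsoon-climate daily record.
Defaults (chosen once as representative of a Southeast-Asian lowland rice
station): annual-mean temperature 27 °C, seasonal half-amplitude 3 °C with
maximum near day 120; AR(1) day-to-day noise φ = 0.7, innovation sd
1.2 °C; diurnal range 9 ± 1.5 °C (the daily jitter keeps tmax- and
tmin-derived indices from being exact duplicates); monthly wet-day
probability rising from 0.10 (dry season) to 0.70 (Jul–Aug); wet-day
amounts Gamma(0.8, 12 mm). Optional: monsoon-onset jitter, linear warming
(°C/decade) and precipitation (%/decade) trends, and constant biases for
bias-correction testing. Random streams are split per (seed, year,
variable), so lengthening a record never perturbs earlier years; the AR(1)
state restarts from its stationary distribution each year (a negligible
1-day seam).

Census series: value = trend × (1 + anomaly/100) with a smooth exponential
trend (area: 10⁶ ha growing 1 %/yr; yield: 3 t/ha growing 1.5 %/yr) and
anomaly = sparse linear signal on full-record-standardized predictors +
Gaussian noise (sd 0.8 points). The default area signal enters through the
wet-season sowing window — CDD −2.0, PRCPTOT +1.5, TXx −1.0 standardized
points — encoding the mechanism the sowing window exists to capture
(pre-planting dry spells shrink planted area, pre-planting rain expands
it); the default yield signal sits in the growing windows (late-growing
TXx −1.5 and R95pTOT −1.0, early-growing PRCPTOT +1.0). The 53 generated
weather years (1960–2012) cover 52 census years (1961–2012), the first
weather year supplying only the lookback months of sowing/wrapped windows.

What the generator does **not** emulate: physically coherent monsoon
dynamics, spatial correlation across locations, interannual climate
persistence beyond the day scale, serially correlated or heteroskedastic
census noise, and policy/price shocks to area. Passing tests therefore show
the pipeline's statistical machinery is correct and well calibrated under
its own assumptions — not that real census data meet those assumptions.

## Problem sizes and numerics

The test suite and the acceptance script use 52-year single-unit records
(27 rolling fits per response; each fit cross-validates 10 mixing values ×
50 penalties × 5 folds), a 20-seed null-calibration ensemble, 200-window
index-oracle sweeps, and 40-year scenario projections — sizes at which
every stage's behaviour is measurable in minutes on one CPU. Quantiles use
linear interpolation between order statistics throughout. Coordinate
descent runs with max_iter = 20000; elastic-net fits are deterministic
given the seed (KFold shuffling and path selection are seeded). Degenerate
inputs (all-dry windows, zero-variance responses or columns, empty
reliability masks, anomalies ≤ −100 %) are handled by the documented
conventions above rather than by exceptions, except where a result would
be meaningless (insufficient wet days for r95/r99, nonpositive trends,
schema mismatches), which raise.
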