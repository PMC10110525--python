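import numpy as np
import pandas as pd
import pytest

import riceclim as rc
from riceclim.model import EnsemblePrediction, standardize_like


def _toy_X(n=30, p=12, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, p)),
        index=pd.Index(np.arange(1961, 1961 + n), name="year"),
        columns=[("s", "sowing", f"I{j}") for j in range(p)],
    )
    return X


class TestFitElasticNet:
    def test_zero_response_gives_null_model(self):
        X = _toy_X()
        fit = rc.fit_elastic_net(X, np.zeros(len(X)))
        assert np.all(fit.coef == 0)
        assert fit.intercept == 0.0
        assert fit.degenerate

    def test_constant_response_flagged(self):
        X = _toy_X()
        fit = rc.fit_elastic_net(X, np.full(len(X), 3.0))
        assert fit.degenerate and fit.intercept == 3.0

    def test_support_recovery_p_larger_than_n(self):
        """With p=162 >> n=25 and two noise-free true columns, those columns
        receive the largest-magnitude coefficients with correct signs."""
        rng = np.random.default_rng(42)
        n, p = 25, 162
        X = pd.DataFrame(
            rng.normal(size=(n, p)),
            index=pd.Index(np.arange(1961, 1961 + n), name="year"),
            columns=[("s", "sowing", f"I{j}") for j in range(p)],
        )
        Z = (X - X.mean()) / X.std(ddof=0)
        y = 0.8 * Z.iloc[:, 1].to_numpy() - 0.5 * Z.iloc[:, 2].to_numpy()
        fit = rc.fit_elastic_net(X, y, seed=0)
        ranked = np.argsort(-np.abs(fit.coef))
        assert set(ranked[:2]) == {1, 2}
        assert fit.coef[1] > 0 > fit.coef[2]

    def test_duplicated_column_leaves_fitted_values_unchanged(self):
        rng = np.random.default_rng(3)
        X = _toy_X(seed=3)
        y = X.iloc[:, 0].to_numpy() + 0.1 * rng.standard_normal(len(X))
        fit1 = rc.fit_elastic_net(X, y, seed=1)
        X2 = X.copy()
        X2[("s", "sowing", "I0_dup")] = X.iloc[:, 0]
        fit2 = rc.fit_elastic_net(X2, y, seed=1)
        pred1 = fit1.predict(X)
        pred2 = fit2.predict(X2)
        assert np.allclose(pred1, pred2, atol=1e-4)

    def test_zero_variance_columns_dropped_with_zero_coef(self):
        X = _toy_X()
        X[("s", "sowing", "CONST")] = 5.0
        y = X.iloc[:, 0].to_numpy()
        fit = rc.fit_elastic_net(X, y, seed=0)
        j = list(X.columns).index(("s", "sowing", "CONST"))
        assert j in fit.dropped_columns
        assert fit.coef[j] == 0.0

    def test_missing_cells_rejected(self):
        X = _toy_X()
        X.iloc[2, 3] = np.nan
        with pytest.raises(ValueError):
            rc.fit_elastic_net(X, np.ones(len(X)))

    def test_standardization_recorded_and_applied(self):
        X = _toy_X()
        y = X.iloc[:, 0].to_numpy()
        fit = rc.fit_elastic_net(X, y, seed=0)
        Z = standardize_like(fit, X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(fit.col_min, X.min().values)
        assert np.allclose(fit.col_max, X.max().values)


class TestRollingOrigin:
    def test_52_year_record_yields_27_models(self, area_ensemble):
        fits, preds = area_ensemble["fits"], area_ensemble["preds"]
        assert len(fits) == 27
        assert preds[0].year == 1986 and preds[-1].year == 2012
        assert all(len(f.training_years) == 25 for f in fits)
        assert list(fits[0].training_years) == list(range(1961, 1986))
        assert list(fits[-1].training_years) == list(range(1987, 2012))

    def test_out_of_sample_structure(self, area_ensemble):
        """No member model's training window contains its target year."""
        fits, preds = area_ensemble["fits"], area_ensemble["preds"]
        for p in preds:
            n_members = len(p.members)
            for f in fits[:n_members]:
                assert p.year not in set(f.training_years)

    def test_26_year_record_single_model(self):
        X = _toy_X(n=26)
        y = np.random.default_rng(0).standard_normal(26)
        fits, preds = rc.rolling_origin_ensemble(X, y, seed=0)
        assert len(fits) == 1 and len(preds) == 1
        assert len(preds[0].members) == 1

    def test_25_year_record_rejected(self):
        X = _toy_X(n=25)
        with pytest.raises(ValueError):
            rc.rolling_origin_ensemble(X, np.zeros(25))

    def test_median_is_exact_sample_median(self, area_ensemble):
        for p in area_ensemble["preds"]:
            assert p.median == np.median(p.members)

    def test_one_step_mode_single_member(self):
        X = _toy_X(n=28)
        y = np.random.default_rng(1).standard_normal(28)
        _, preds = rc.rolling_origin_ensemble(X, y, seed=0, mode="one_step")
        assert all(len(p.members) == 1 for p in preds)


class TestValidationMetrics:
    def _pred(self, years, vals):
        return [
            EnsemblePrediction("u", "area", int(y), np.array([v]), float(v))
            for y, v in zip(years, vals)
        ]

    def test_perfect_prediction(self):
        years = np.arange(2000, 2010)
        obs = rc.AnomalySeries(years, np.ones(10),
                               np.sin(np.arange(10, dtype=float)))
        vm = rc.validation_metrics(self._pred(years, obs.anomaly_pct), obs)
        assert vm.R == pytest.approx(1.0)
        assert vm.rmse == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift_keeps_r_sets_rmse(self):
        years = np.arange(2000, 2010)
        o = np.sin(np.arange(10, dtype=float))
        obs = rc.AnomalySeries(years, np.ones(10), o)
        vm = rc.validation_metrics(self._pred(years, o + 1.0), obs)
        assert vm.R == pytest.approx(1.0)
        assert vm.rmse == pytest.approx(1.0)

    def test_sign_flip(self):
        years = np.arange(2000, 2010)
        o = np.sin(np.arange(10, dtype=float))
        obs = rc.AnomalySeries(years, np.ones(10), o)
        vm = rc.validation_metrics(self._pred(years, -o), obs)
        assert vm.R == pytest.approx(-1.0)


class TestCoefficientAggregation:
    def _fit(self, coef, cols=None):
        cols = cols or [("s", "sowing", f"I{j}") for j in range(len(coef))]
        return rc.ModelFit(
            unit_id="u", response="area",
            training_years=np.arange(25), columns=cols,
            coef=np.asarray(coef, dtype=float), intercept=0.0,
            l1_ratio=0.5, alpha=0.1,
            col_mean=np.zeros(len(coef)), col_sd=np.ones(len(coef)),
            col_min=np.zeros(len(coef)), col_max=np.ones(len(coef)),
        )

    def test_arithmetic_mean_across_units(self):
        avg = rc.aggregate_country_coefficients(
            [self._fit([1.0, -1.0]), self._fit([3.0, 1.0])])
        assert np.allclose(avg.values, [2.0, 0.0])

    def test_single_unit_identity_and_permutation_invariance(self):
        f1, f2 = self._fit([1.0, 2.0]), self._fit([0.0, -2.0])
        assert np.allclose(
            rc.aggregate_country_coefficients([f1]).values, [1.0, 2.0])
        a = rc.aggregate_country_coefficients([f1, f2]).values
        b = rc.aggregate_country_coefficients([f2, f1]).values
        assert np.allclose(a, b)

    def test_schema_mismatch_rejected(self):
        f1 = self._fit([1.0, 2.0])
        f2 = self._fit([1.0, 2.0], cols=[("s", "sowing", "A"),
                                         ("s", "sowing", "B")])
        with pytest.raises(ValueError):
            rc.aggregate_country_coefficients([f1, f2])


class TestTopContributors:
    def test_ranking_and_sign(self):
        s = pd.Series([0.5, 0.3, -0.4, 0.2, 0.1, -0.6],
                      index=[f"c{j}" for j in range(6)])
        assert rc.top_contributors(s, "positive", 3) == ["c0", "c1", "c3"]
        assert rc.top_contributors(s, "negative", 2) == ["c5", "c2"]

    def test_all_zero_vector_empty(self):
        s = pd.Series(np.zeros(4), index=list("abcd"))
        assert rc.top_contributors(s, "positive") == []

    def test_fewer_than_k_returns_fewer(self):
        s = pd.Series([0.5, -0.1, 0.0, 0.0], index=list("abcd"))
        assert rc.top_contributors(s, "positive", 3) == ["a"]

    def test_ties_broken_by_column_order(self):
        s = pd.Series([0.5, 0.5, 0.5, 0.5], index=list("abcd"))
        assert rc.top_contributors(s, "positive", 2) == ["a", "b"]


class TestRepresentativeCell:
    def test_argmax_dict(self):
        assert rc.pick_representative_cell({"A": 10, "B": 30, "C": 5}) == "B"

    def test_single_cell(self):
        assert rc.pick_representative_cell({"only": 1.0}) == "only"

    def test_tie_first_by_order(self):
        assert rc.pick_representative_cell({"B": 10, "A": 10}) == "A"
        grid = np.array([[0.0, 10.0], [10.0, 0.0]])
        assert rc.pick_representative_cell(grid) == (0, 1)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            rc.pick_representative_cell({"A": 0.0, "B": 0.0})
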