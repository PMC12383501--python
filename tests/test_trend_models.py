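import numpy as np
import pandas as pd
import pytest

from tropicatch.thermal_mtc import classify_affinity, compute_mtc
from tropicatch.trend_models import (
    ModelChoice,
    SplineFit,
    TrendFit,
    _penalized_solve,
    _curvature_penalty,
    _spline_basis,
    choose_trend_model,
    compare_slopes_ancova,
    fit_lagged,
    fit_linear_trend,
    fit_spline_trend,
    sensitivity_loo,
)

YEARS = pd.Index(range(2000, 2010), name="year")


def series_of(values, years=None):
    return pd.Series(np.asarray(values, float), index=years if years is not None else YEARS[: len(values)])


class TestLinearTrend:
    def test_exact_line(self):
        t = np.arange(10)
        fit = fit_linear_trend(series_of(2 * t + 1, YEARS))
        assert fit.slope == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.p_value < 1e-12

    def test_constant(self):
        fit = fit_linear_trend(series_of([3.0] * 5))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == 0.0 and fit.p_value == 1.0

    def test_closed_form_oracle(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=10)
        x = YEARS.to_numpy(float)
        slope_oracle = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept_oracle = y.mean() - slope_oracle * x.mean()
        fit = fit_linear_trend(series_of(y, YEARS))
        assert fit.slope == pytest.approx(slope_oracle, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept_oracle, abs=1e-10)

    def test_residuals_sum_to_zero(self):
        fit = fit_linear_trend(series_of(np.random.default_rng(2).normal(size=8)))
        assert fit.residuals.sum() == pytest.approx(0.0, abs=1e-9)
        assert fit.adj_r2 <= fit.r2 + 1e-12

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_linear_trend(series_of([1.0, 2.0]))
        same_year = pd.Series([1.0, 2.0, 3.0], index=[2000, 2000, 2000])
        with pytest.raises(ValueError):
            fit_linear_trend(same_year)

    def test_mean_shift_invariance(self):
        y = series_of(np.random.default_rng(3).normal(size=10))
        assert fit_linear_trend(y).slope == pytest.approx(
            fit_linear_trend(y + 100.0).slope, abs=1e-9
        )


class TestSplineTrend:
    def test_straight_line_any_lambda(self):
        y = series_of(0.5 * np.arange(10) + 2, YEARS)
        for lam in (0.0, 1.0, 1e6):
            fit = fit_spline_trend(y, lam=lam)
            assert np.allclose(fit.fitted, y, atol=1e-7)
        assert fit_spline_trend(y, lam=1e10).edf == pytest.approx(2.0, abs=1e-4)

    def test_lambda_zero_equals_unpenalized_basis_regression(self):
        rng = np.random.default_rng(4)
        y = series_of(rng.normal(size=12), pd.Index(range(2000, 2012)))
        fit = fit_spline_trend(y, lam=0.0)
        x = (y.index.to_numpy(float) - 2000) / 11.0
        design, _ = _spline_basis(x, 5)
        coef, *_ = np.linalg.lstsq(design, y.to_numpy(), rcond=None)
        assert np.allclose(fit.fitted, design @ coef, atol=1e-8)

    def test_infinite_lambda_converges_to_ols_line(self):
        rng = np.random.default_rng(5)
        years = pd.Index(range(1978, 2019))
        y = series_of(0.01 * np.arange(41) + rng.normal(0, 0.2, 41), years)
        lin = fit_linear_trend(y)
        spl = fit_spline_trend(y, lam=1e10)
        assert np.abs(spl.fitted - lin.fitted).max() < 1e-6

    def test_gcv_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(6)
        t = np.arange(30)
        y = series_of(
            0.05 * t + np.sin(t / 4.0) + rng.normal(0, 0.3, 30),
            pd.Index(range(1990, 2020)),
        )
        fit = fit_spline_trend(y)
        # oracle: dense grid over the same lambda range
        x = (y.index.to_numpy(float) - 1990) / 29.0
        design, knots = _spline_basis(x, 5)
        penalty = _curvature_penalty(knots, 5)
        grid = np.logspace(-8, 12, 4001)
        yy = y.to_numpy()
        n = len(yy)

        def gcv(lam):
            _, edf, rss = _penalized_solve(design, penalty, yy, lam)
            return n * rss / (n - edf) ** 2

        best = min(grid, key=gcv)
        # selected lambda matches the grid winner to grid resolution
        assert abs(np.log10(fit.lam) - np.log10(best)) < 0.01
        assert fit.gcv <= gcv(best) * (1 + 1e-9)

    def test_edf_bounds(self):
        rng = np.random.default_rng(7)
        y = series_of(rng.normal(size=20), pd.Index(range(2000, 2020)))
        fit = fit_spline_trend(y)
        assert 2.0 - 1e-6 <= fit.edf <= 5.0 + 1e-6

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_spline_trend(series_of([1.0, 2.0, 3.0, 4.0]), k=5)


def _fake_fits(d_aic, d_bic, d_adj):
    idx = pd.Index(range(5))
    resid = pd.Series(np.zeros(5), index=idx)
    fitted = pd.Series(np.zeros(5), index=idx)
    lin = TrendFit(0, 0, 0, 1, 0.5, 0.4, 100.0, 103.0, 5, resid, fitted)
    spl = SplineFit(5, 1.0, 3.0, 1.0, 100.0 + d_aic, 103.0 + d_bic, 1.0, 5, fitted, resid, 0.4 + d_adj)
    return lin, spl


class TestModelChoice:
    def test_linear_truth_usually_selects_linear(self):
        # noisy draws can genuinely look curved; check the typical case
        # over several seeds rather than any single realization
        picks = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = series_of(
                0.3 * np.arange(30) + rng.normal(0, 0.3, 30),
                pd.Index(range(1990, 2020)),
            )
            picks.append(
                choose_trend_model(fit_linear_trend(y), fit_spline_trend(y)).selected
            )
        assert picks.count("linear") >= 7

    def test_noiseless_line_selects_linear(self):
        y = series_of(0.3 * np.arange(12) + 1.0, pd.Index(range(2000, 2012)))
        choice = choose_trend_model(fit_linear_trend(y), fit_spline_trend(y))
        assert choice.selected == "linear"

    def test_disagreement_retains_linear(self):
        lin, spl = _fake_fits(d_aic=-5.0, d_bic=+2.0, d_adj=0.1)
        assert choose_trend_model(lin, spl).selected == "linear"

    def test_spline_wins_all_criteria(self):
        # strong step change: the spline beats the line on AIC, BIC, adj R2
        years = pd.Index(range(1980, 2020))
        y = series_of(np.r_[np.zeros(20), np.ones(20) * 5.0], years)
        lin = fit_linear_trend(y)
        spl = fit_spline_trend(y)
        choice = choose_trend_model(lin, spl)
        assert choice.delta_aic < 0 and choice.delta_bic < 0 and choice.delta_adj_r2 > 0
        assert choice.selected == "spline"

    def test_mismatched_data_errors(self):
        a = series_of(np.arange(10, dtype=float), YEARS)
        b = series_of(np.arange(12, dtype=float), pd.Index(range(2000, 2012)))
        with pytest.raises(ValueError):
            choose_trend_model(fit_linear_trend(a), fit_spline_trend(b))


class TestAncova:
    def test_duplicated_series(self):
        y = series_of(np.random.default_rng(9).normal(size=10), YEARS)
        res = compare_slopes_ancova(y, y)
        assert res.slope_difference == pytest.approx(0.0, abs=1e-10)
        assert res.interaction_p > 0.99

    def test_noiseless_different_slopes(self):
        t = np.arange(10, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            res = compare_slopes_ancova(series_of(t, YEARS), series_of(2 * t, YEARS))
        assert res.slope_difference == pytest.approx(1.0, abs=1e-9)
        assert res.interaction_p < 1e-9
        assert res.slope_a == pytest.approx(1.0) and res.slope_b == pytest.approx(2.0)

    def test_label_mapping_independent_of_alphabet(self):
        t = np.arange(10, dtype=float)
        noise = np.random.default_rng(10).normal(0, 0.5, 10)
        res = compare_slopes_ancova(
            series_of(3 * t + noise, YEARS),
            series_of(1 * t - noise, YEARS),
            labels=("ZZZ", "AAA"),
        )
        assert res.slope_a > res.slope_b

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            compare_slopes_ancova(series_of([1.0, 2.0]), series_of(np.arange(5.0)))


class TestSensitivity:
    def make_inputs(self):
        # cold species declines; warm species stable: trend driven by A
        years = pd.Index(range(2000, 2010), name="year")
        matrix = pd.DataFrame(
            {
                "A": np.linspace(100, 10, 10),  # cold, declining
                "B": np.full(10, 50.0),  # warm
                "C": np.full(10, 30.0),  # warm
            },
            index=years,
        )
        table = classify_affinity({"A": 15.0, "B": 27.0, "C": 26.0})
        return matrix, table

    def test_removal_kills_trend(self):
        matrix, table = self.make_inputs()
        rows = sensitivity_loo(matrix, table).set_index("species_code")
        # oracle: recompute from scratch without the driver species
        oracle = fit_linear_trend(compute_mtc(matrix.drop(columns="A"), table)).slope
        assert rows.loc["A", "slope_without"] == pytest.approx(oracle, abs=1e-12)
        # dropping the declining cold species kills the upward trend
        assert oracle == pytest.approx(0.0, abs=1e-9)
        assert rows.loc["A", "flagged"]

    def test_zero_biomass_species_reproduces_full_slope(self):
        matrix, table = self.make_inputs()
        matrix = matrix.assign(D=0.0)
        table = classify_affinity(
            {"A": 15.0, "B": 27.0, "C": 26.0, "D": 22.0}
        )
        rows = sensitivity_loo(matrix, table).set_index("species_code")
        assert rows.loc["D", "slope_change_pct"] == pytest.approx(0.0, abs=1e-9)
        assert not rows.loc["D", "flagged"]

    def test_signed_percent_change(self):
        matrix, table = self.make_inputs()
        res = sensitivity_loo(matrix, table)
        full = res.attrs["slope_full"]
        rows = res.set_index("species_code")
        without = rows.loc["A", "slope_without"]
        assert rows.loc["A", "slope_change_pct"] == pytest.approx(
            100.0 * (without - full) / abs(full)
        )

    def test_needs_three_species(self):
        years = pd.Index(range(2000, 2005), name="year")
        matrix = pd.DataFrame({"A": np.ones(5), "B": np.ones(5)}, index=years)
        with pytest.raises(ValueError):
            sensitivity_loo(matrix, classify_affinity({"A": 20.0, "B": 28.0}))

    def test_unavailable_when_too_few_left(self):
        years = pd.Index(range(2000, 2006), name="year")
        matrix = pd.DataFrame(
            {"A": np.ones(6), "B": [1, 1, 1, 0, 0, 0], "C": [0, 0, 0, 1, 1, 1]},
            index=years,
        ).astype(float)
        table = classify_affinity({"A": 20.0, "B": 25.0, "C": 27.0})
        rows = sensitivity_loo(matrix, table).set_index("species_code")
        assert not rows.loc["B", "available"]  # years 2003-05 keep only A


class TestLaggedModels:
    def test_shift_recovery(self):
        rng = np.random.default_rng(11)
        years = np.arange(1980, 2020)
        driver = pd.Series(rng.normal(size=40), index=years)
        response = pd.Series(
            2.5 * driver.to_numpy(), index=years + 2
        )  # response_y = 2.5 * driver_{y-2}
        fits, selection = fit_lagged(response, driver, max_lag=4)
        best = {f.lag: f for f in fits}[2]
        assert best.r2 == pytest.approx(1.0)
        assert best.slope == pytest.approx(2.5)
        assert selection.by_aic == 2 and selection.by_r2 == 2

    def test_alignment_counts(self):
        years = np.arange(2000, 2020)
        response = pd.Series(np.random.default_rng(12).normal(size=20), index=years)
        driver = pd.Series(np.random.default_rng(13).normal(size=20), index=years)
        fits, _ = fit_lagged(response, driver, max_lag=4)
        assert [f.n for f in fits] == [20, 19, 18, 17, 16]

    def test_common_sample(self):
        years = np.arange(2000, 2020)
        response = pd.Series(np.random.default_rng(14).normal(size=20), index=years)
        driver = pd.Series(np.random.default_rng(15).normal(size=20), index=years)
        fits, selection = fit_lagged(response, driver, max_lag=4, common_sample=True)
        assert {f.n for f in fits} == {16}
        assert selection.common_sample

    def test_anomaly_invariance_of_slope(self):
        years = np.arange(2000, 2020)
        rng = np.random.default_rng(16)
        response = pd.Series(rng.normal(10, 1, 20), index=years)
        driver = pd.Series(rng.normal(50, 2, 20), index=years)
        raw, _ = fit_lagged(response, driver, max_lag=2)
        anom, _ = fit_lagged(response - response.mean(), driver - driver.mean(), max_lag=2)
        for f_raw, f_anom in zip(raw, anom):
            assert f_raw.slope == pytest.approx(f_anom.slope, abs=1e-9)

    def test_insufficient_overlap_skipped(self):
        response = pd.Series([1.0, 2.0, 3.0, 4.0], index=[2000, 2001, 2002, 2003])
        driver = pd.Series([1.0, 2.0, 3.0, 4.0], index=[2000, 2001, 2002, 2003])
        fits, _ = fit_lagged(response, driver, max_lag=3)
        assert [f.lag for f in fits] == [0, 1]  # lags 2,3 leave < 3 pairs

    def test_no_overlap_errors(self):
        response = pd.Series([1.0, 2.0, 3.0], index=[2000, 2001, 2002])
        driver = pd.Series([1.0, 2.0, 3.0], index=[2050, 2051, 2052])
        with pytest.raises(ValueError):
            fit_lagged(response, driver, max_lag=1)

    def test_null_rejection_rate(self):
        # white-noise driver and response: ~5% of lag-0 slopes significant
        rng = np.random.default_rng(17)
        years = np.arange(1978, 2018)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            response = pd.Series(rng.normal(size=40), index=years)
            driver = pd.Series(rng.normal(size=40), index=years)
            fits, _ = fit_lagged(response, driver, max_lag=0)
            hits += fits[0].p_value < 0.05
        assert 0.02 < hits / n_rep < 0.08
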