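"""Rating model, unit conversion, flow normalization and uncertainty."""

import numpy as np
import pandas as pd
import pytest

import estuarylink as el
from estuarylink.errors import FitError, RangeError, ValidationError
from estuarylink.load_model import CFS_MGL_TO_KG_PER_DAY


class TestSubstituteCensored:
    def _series(self):
        data = pd.DataFrame(
            {
                "date": pd.date_range("2005-01-01", periods=10, freq="91D"),
                "value": [0.21, 0.05, 0.3, 0.4, 0.05, 0.2, 0.25, 0.31, 0.18, 0.22],
                "censored": [False, True, False, False, True] + [False] * 5,
                "detection_limit": [np.nan, 0.05, np.nan, np.nan, 0.05] + [np.nan] * 5,
            }
        )
        return el.SampleSeries(station_id="s", parameter="TP", data=data)

    def test_half_detection_limit_rule(self):
        out = el.substitute_censored(self._series())
        assert np.allclose(out.data.loc[out.data["censored"], "value"], 0.025)

    def test_uncensored_unchanged_and_count_conserved(self):
        before = self._series()
        out = el.substitute_censored(before)
        changed = (out.data["value"] != before.data["value"]).sum()
        assert changed == 2
        assert out.data.loc[0, "value"] == 0.21

    def test_missing_detection_limit_rejected_at_construction(self):
        data = pd.DataFrame(
            {"date": ["2005-01-01"], "value": [0.05], "censored": [True],
             "detection_limit": [np.nan]}
        )
        with pytest.raises(ValidationError):
            el.SampleSeries(station_id="s", parameter="TP", data=data)


class TestConcentrationToLoad:
    def test_unit_oracle(self):
        # 1 mg/L at 1 cfs: 28.316846592 L/s * 86400 s * 1e-6 kg/mg
        assert el.concentration_to_load(1.0, 1.0) == pytest.approx(2.446576, abs=5e-7)

    def test_zero_concentration(self):
        assert el.concentration_to_load(0.0, 500.0) == 0.0

    def test_linear_scaling(self):
        assert el.concentration_to_load(0.2, 500.0) == pytest.approx(244.6576, abs=5e-5)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            el.concentration_to_load(-0.1, 1.0)


class TestFitAndPredict:
    def test_null_model_recovers_intercept(self, flow17, cov17):
        config = el.ConcGenConfig(seed=30, intercept=np.log(0.25), noise_sd=1e-4,
                                  detection_limit=1e-6, sampling_interval_days=30)
        samples = el.generate_concentration_samples(flow17, config)
        model = el.fit_concentration_model(
            el.substitute_censored(samples), cov17, optimizer_maxfev=60
        )
        assert model.coefficients[0] == pytest.approx(np.log(0.25), abs=0.01)
        assert sum(model.edof_per_term.values()) < 1.0
        pred = el.predict_daily_concentration(model, cov17[~cov17["warmup"]])
        assert np.allclose(pred, 0.25, rtol=0.02)

    def test_monotone_flow_effect_sign(self, rating_model, pred_cov17):
        q = pred_cov17["log1pQ"].to_numpy()
        lo, hi = np.quantile(q, [0.2, 0.8])
        effect = rating_model.partial_effect("log1pQ", np.array([lo, hi]))
        assert effect[1] > effect[0]  # generating flow effect is increasing

    def test_refit_deterministic(self, samples17, cov17, rating_model):
        again = el.fit_concentration_model(
            el.substitute_censored(samples17), cov17, optimizer_maxfev=80
        )
        assert np.allclose(again.coefficients, rating_model.coefficients, atol=1e-8)

    def test_too_few_samples_refused(self, flow17, cov17):
        config = el.ConcGenConfig(seed=31, sampling_interval_days=365)
        samples = el.generate_concentration_samples(flow17, config)
        with pytest.raises(FitError, match="usable samples"):
            el.fit_concentration_model(el.substitute_censored(samples), cov17)

    def test_prediction_requires_covariates(self, rating_model):
        with pytest.raises(ValidationError):
            rating_model.predict_response(pd.DataFrame({"ddate": [2005.0]}))

    def test_predictions_strictly_positive(self, rating_model, pred_cov17):
        pred = el.predict_daily_concentration(rating_model, pred_cov17)
        assert (pred > 0).all()


class TestLakeOutlet:
    def test_zero_release_zero_load(self, flow17):
        dates = flow17.dates[400:410]
        conc = pd.Series(0.5, index=dates)
        release = el.DischargeSeries(dates=flow17.dates, flows=np.zeros(len(flow17)))
        out = el.lake_outlet_daily_load(conc, release)
        assert np.allclose(out["load_kg"], 0.0)

    def test_identical_series_match_standard_pathway(self, rating_model, pred_cov17, flow17):
        conc = el.predict_daily_concentration(rating_model, pred_cov17)
        via_outlet = el.lake_outlet_daily_load(conc, flow17)
        standard = el.estimate_daily_loads(rating_model, pred_cov17, flow17)
        assert np.allclose(via_outlet["load_kg"], standard["load_kg"])

    def test_smoothed_release_scales_load_by_volume_ratio(self, flow17):
        # constant concentration: annual load ratio == release/inflow volume ratio
        release_flows = (
            pd.Series(flow17.flows).rolling(30, min_periods=1).mean().to_numpy()
        )
        release = el.DischargeSeries(dates=flow17.dates, flows=release_flows)
        conc = pd.Series(0.2, index=flow17.dates)
        inflow_load = el.lake_outlet_daily_load(conc, flow17)
        outlet_load = el.lake_outlet_daily_load(conc, release)
        got = outlet_load["load_kg"].sum() / inflow_load["load_kg"].sum()
        want = release.flows.sum() / flow17.flows.sum()
        assert got == pytest.approx(want, rel=1e-9)

    def test_date_mismatch_raises(self, flow17):
        conc = pd.Series(0.5, index=pd.date_range("1980-01-01", periods=5, freq="D"))
        with pytest.raises(RangeError):
            el.lake_outlet_daily_load(conc, flow17)


class TestFlowNormalize:
    def test_single_year_record_equals_delivered(self):
        flow = el.generate_discharge(el.FlowGenConfig(seed=40, n_years=3))
        config = el.ConcGenConfig(seed=41, intercept=np.log(0.2), noise_sd=0.02,
                                  sampling_interval_days=10)
        samples = el.generate_concentration_samples(flow, config)
        cov = el.build_covariates(flow)
        model = el.fit_concentration_model(
            el.substitute_censored(samples), cov, optimizer_maxfev=40
        )
        # restrict to a single complete year: one historical tuple per day
        one_year = cov[(cov["date"] >= "2001-01-01") & (cov["date"] <= "2001-12-31")]
        one_year = one_year.reset_index(drop=True)
        fn = el.flow_normalize(model, one_year)
        delivered = el.estimate_daily_loads(model, one_year, flow)
        assert np.allclose(fn["fn_load_kg"], delivered["load_kg"], rtol=1e-10)

    def test_flat_flow_smooths_fn_equals_prediction(self, rating_model, pred_cov17):
        from dataclasses import replace

        model = replace(rating_model, coefficients=rating_model.coefficients.copy())
        for name in ("log1pQ", "ma", "fa"):
            model.coefficients[model._term_slices[name]] = 0.0
        fn = el.flow_normalize(model, pred_cov17)
        pred = el.predict_daily_concentration(model, pred_cov17)
        assert np.allclose(fn["fn_conc_mgl"], pred.to_numpy(), rtol=1e-8)

    def test_conc_only_normalization_uses_own_flow(self, rating_model, pred_cov17):
        fn = el.flow_normalize(model=rating_model, covariates=pred_cov17,
                               normalize_load_flow=False)
        expect = fn["fn_conc_mgl"] * pred_cov17["flow_cfs"] * CFS_MGL_TO_KG_PER_DAY
        assert np.allclose(fn["fn_load_kg"], expect)


class TestAggregateAnnual:
    def test_non_leap_and_leap_year_day_counts(self):
        d1 = pd.DataFrame({"date": pd.date_range("2019-01-01", "2019-12-31"), "load_kg": 1.0})
        d2 = pd.DataFrame({"date": pd.date_range("2020-01-01", "2020-12-31"), "load_kg": 1.0})
        assert el.aggregate_annual(d1)["load_kg"].iloc[0] == 365.0
        assert el.aggregate_annual(d2)["load_kg"].iloc[0] == 366.0

    def test_partial_years_excluded_and_reported(self):
        daily = pd.DataFrame(
            {"date": pd.date_range("2019-06-01", "2020-12-31"), "load_kg": 1.0}
        )
        out = el.aggregate_annual(daily)
        assert out["year"].tolist() == [2020]
        assert out.attrs["partial_years"] == [2019]

    def test_linearity_sum_then_aggregate(self, rating_model, pred_cov17, flow17):
        daily = el.estimate_daily_loads(rating_model, pred_cov17, flow17)
        doubled = daily.assign(load_kg=2 * daily["load_kg"])
        a1 = el.aggregate_annual(daily)["load_kg"].to_numpy()
        a2 = el.aggregate_annual(doubled)["load_kg"].to_numpy()
        assert np.allclose(a2, 2 * a1)


class TestPosteriorIntervals:
    def test_zero_covariance_collapses_to_plugin(self, rating_model, pred_cov17):
        from dataclasses import replace

        model = replace(
            rating_model,
            coefficient_covariance=np.zeros_like(rating_model.coefficient_covariance),
        )
        out = el.posterior_annual_intervals(model, pred_cov17, n_draws=200, seed=0)
        assert np.allclose(out["lower90"], out["load_kg"], rtol=1e-10)
        assert np.allclose(out["upper90"], out["load_kg"], rtol=1e-10)
        assert np.allclose(out["sd"], 0.0)

    def test_draw_count_stability(self, rating_model, pred_cov17):
        big = el.posterior_annual_intervals(rating_model, pred_cov17, n_draws=8000, seed=7)
        small = el.posterior_annual_intervals(rating_model, pred_cov17, n_draws=1000, seed=3)
        assert np.allclose(big["lower90"], small["lower90"], rtol=0.02)
        assert np.allclose(big["upper90"], small["upper90"], rtol=0.02)

    def test_interval_ordering_and_api_guards(self, rating_model, pred_cov17):
        out = el.posterior_annual_intervals(rating_model, pred_cov17, n_draws=150, seed=2)
        assert (out["lower90"] <= out["upper90"]).all()
        assert (out["load_kg"] > 0).all()
        with pytest.raises(ValidationError):
            el.posterior_annual_intervals(rating_model, pred_cov17, n_draws=50)
        with pytest.raises(ValidationError):
            el.posterior_annual_intervals(rating_model, pred_cov17, target="monthly")

    def test_non_psd_covariance_rejected_with_hint(self, rating_model):
        from dataclasses import replace

        model = replace(
            rating_model,
            coefficient_covariance=rating_model.coefficient_covariance.copy(),
        )
        model.coefficient_covariance[0, 0] = -1.0
        with pytest.raises(ValidationError, match="allow_repair"):
            model.posterior_coefficient_draws(100, seed=0)
        draws = model.posterior_coefficient_draws(100, seed=0, allow_repair=True)
        assert draws.shape[0] == 100
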