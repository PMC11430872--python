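"""Moisture ratio, thin-layer model fitting, ranking, and time inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rwdry.kinetics import (
    DryingRun,
    MoistureSeries,
    drying_time_to_target,
    evaluate_fit,
    fit_all_models,
    fit_thin_layer_model,
    moisture_ratio,
    rank_models,
)


def _run_from_mr(time_min, mr, m_dry=2.0, x0=4.0, temp=60.0):
    mass = m_dry * (1.0 + np.asarray(mr) * x0)
    return DryingRun("r", temp, np.asarray(time_min, float), mass, m_dry)


class TestMoistureRatio:
    def test_hand_arithmetic(self):
        # 10 g at 80% w.b.: m_dry = 2 g, X0 = 4; at 6 g, X = 2 so MR = 0.5
        run = DryingRun("r", 50.0, [0.0, 10.0], [10.0, 6.0], 2.0)
        s = moisture_ratio(run)
        assert s.mr[0] == 1.0
        assert s.mr[1] == pytest.approx(0.5, abs=1e-12)

    def test_equilibrium_point_is_zero(self):
        run = DryingRun("r", 50.0, [0.0, 10.0], [10.0, 2.0], 2.0)
        assert moisture_ratio(run).mr[1] == pytest.approx(0.0, abs=1e-12)

    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_mass_rescaling(self, scale):
        t = [0.0, 5.0, 10.0]
        m = np.array([10.0, 7.0, 4.0])
        a = moisture_ratio(DryingRun("a", 50.0, t, m, 2.0)).mr
        b = moisture_ratio(DryingRun("b", 50.0, t, m * scale, 2.0 * scale)).mr
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_initial_moisture_at_equilibrium_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            moisture_ratio(DryingRun("r", 50.0, [0.0, 5.0], [2.0, 2.0], 2.0))


class TestEvaluateFit:
    def test_perfect_fit(self):
        out = evaluate_fit([1.0, 0.5, 0.0], [1.0, 0.5, 0.0])
        assert out["mse"] == 0.0 and out["r2"] == 1.0

    def test_null_model_baseline(self):
        exp = np.array([1.0, 0.5, 0.0])
        out = evaluate_fit(exp, np.full(3, exp.mean()))
        assert out["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        out = evaluate_fit([1.0, 0.5, 0.0], [0.9, 0.5, 0.1])
        assert out["mse"] == pytest.approx(0.02 / 3, rel=1e-12)
        assert out["r2"] == pytest.approx(1 - 0.02 / 0.5, rel=1e-12)

    def test_zero_variance_flagged_as_nan(self):
        assert np.isnan(evaluate_fit([0.5, 0.5], [0.4, 0.6])["r2"])


class TestThinLayerFitting:
    def test_page_exact_recovery(self):
        t = np.arange(0, 101, 5.0)
        mr = np.exp(-0.05 * t**1.2)
        fit = fit_thin_layer_model(MoistureSeries(t, mr), "page")
        assert fit.converged
        assert fit.params["k"] == pytest.approx(0.05, rel=1e-6)
        assert fit.params["n"] == pytest.approx(1.2, rel=1e-6)

    def test_newton_is_nested_in_page(self):
        t = np.arange(0, 101, 5.0)
        mr = np.exp(-0.05 * t**1.2)
        series = MoistureSeries(t, mr)
        page = fit_thin_layer_model(series, "page")
        newton = fit_thin_layer_model(series, "newton")
        assert page.mse < newton.mse

    def test_wang_singh_quadratic_closed_form(self):
        # linear-in-parameters model: normal equations are the oracle
        t = np.arange(0, 101, 5.0)
        mr = 1.0 - 0.01 * t + 0.00002 * t**2
        design = np.column_stack([t, t**2])
        a_hat, b_hat = np.linalg.lstsq(design, mr - 1.0, rcond=None)[0]
        fit = fit_thin_layer_model(MoistureSeries(t, mr), "wang_singh")
        assert fit.params["a"] == pytest.approx(a_hat, abs=1e-8)
        assert fit.params["b"] == pytest.approx(b_hat, abs=1e-10)
        assert fit.params["a"] == pytest.approx(-0.01, abs=1e-8)

    def test_nested_model_sse_dominance(self):
        rng = np.random.default_rng(42)
        t = np.arange(0, 121, 5.0)
        for _ in range(10):
            mr = np.exp(-rng.uniform(0.01, 0.05) * t ** rng.uniform(0.9, 1.3))
            mr = np.clip(mr + rng.normal(0, 0.01, t.size), 0, 1)
            series = MoistureSeries(t, mr)
            sse = {m: fit_thin_layer_model(series, m).sse
                   for m in ("newton", "page", "henderson_pabis", "two_term")}
            tol = 1e-9 + 1e-6 * sse["newton"]
            assert sse["page"] <= sse["newton"] + tol
            assert sse["henderson_pabis"] <= sse["newton"] + tol
            assert sse["two_term"] <= sse["henderson_pabis"] + tol

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            fit_thin_layer_model(MoistureSeries([0.0, 5.0, 10.0], [1.0, 0.5, 0.2]), "two_term")

    def test_fitted_page_k_positive_and_bounded_prediction(self, noiseless_bundle):
        from rwdry.kinetics import moisture_ratio as mratio

        run = noiseless_bundle.drying_runs[0]
        fit = fit_thin_layer_model(mratio(run), "page")
        assert fit.params["k"] > 0
        pred = fit.predict(run.time_min)
        assert np.all(pred >= 0.0) and np.all(pred <= 1.0 + 1e-9)


class TestRanking:
    def _mk(self, name, r2, mse, n_par, converged=True):
        from rwdry.kinetics import ThinLayerResults

        return ThinLayerResults(name, dict.fromkeys(list("abck")[:n_par], 1.0),
                                r2, mse, converged, 20)

    def test_single_fit(self):
        f = self._mk("page", 0.99, 0.01, 2)
        assert rank_models([f]) == [f]

    def test_higher_r2_first(self):
        page = self._mk("page", 0.9990, 0.0149, 2)
        newton = self._mk("newton", 0.9797, 0.0582, 1)
        assert rank_models([newton, page])[0].model_name == "page"

    def test_tie_broken_by_fewer_parameters(self):
        a = self._mk("henderson_pabis", 0.99, 0.01, 2)
        b = self._mk("logarithmic", 0.99, 0.01, 3)
        assert rank_models([b, a])[0].model_name == "henderson_pabis"

    def test_non_converged_last(self):
        good = self._mk("newton", 0.90, 0.05, 1)
        bad = self._mk("page", 0.999, 0.001, 2, converged=False)
        assert rank_models([bad, good])[-1].model_name == "page"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_models([])


class TestDryingTimeToTarget:
    def _page_fit(self, k, n):
        t = np.arange(0, 301, 5.0)
        return fit_thin_layer_model(MoistureSeries(t, np.exp(-k * t**n)), "page")

    def test_closed_form_newton_case(self):
        fit = self._page_fit(0.05, 1.0)
        assert drying_time_to_target(fit, 0.5) == pytest.approx(np.log(2) / 0.05, abs=1e-6)

    def test_target_one_is_time_zero(self):
        fit = self._page_fit(0.05, 1.0)
        assert drying_time_to_target(fit, 0.999999) == pytest.approx(0.0, abs=1e-3)

    def test_bisection_matches_closed_form(self):
        k, n = 0.02, 1.3
        fit = self._page_fit(k, n)
        closed = (-np.log(0.05) / fit.params["k"]) ** (1.0 / fit.params["n"])
        assert drying_time_to_target(fit, 0.05) == pytest.approx(closed, abs=1e-6)

    def test_unreachable_target_fails(self):
        # upward-turning quadratic never reaches a tiny MR
        t = np.arange(0, 101, 5.0)
        mr = 1.0 - 0.01 * t + 0.00008 * t**2
        fit = fit_thin_layer_model(MoistureSeries(t, mr), "wang_singh")
        with pytest.raises(ValueError, match="never reaches"):
            drying_time_to_target(fit, 1e-6, t_max=1e4)


def test_fit_all_models_ranks_page_first_on_page_data(noiseless_bundle):
    series = moisture_ratio(noiseless_bundle.drying_runs[0])
    ranked = fit_all_models(series)
    assert ranked[0].model_name == "page"
    assert len(ranked) == 6
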