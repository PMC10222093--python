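"""Least-squares fitting, goodness of fit, intervals and model ranking."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from implantpk import (
    FitOptions,
    ImplantSpec,
    ObservationSet,
    ParameterSet,
    adjusted_r_squared,
    compare_models,
    cumulative_release,
    fit_release_model,
    objective_sse,
    parameter_cis,
    prediction_band,
)
from implantpk.synthetic import SyntheticConfig, generate_ex_vivo, generate_label_rates

from conftest import BIEXP_TRUTH, FAMILY_TRUTHS, FIRST_ORDER_TRUTH

QUARTERLY = np.array(
    [0.0, 91.0, 182.0, 274.0, 365.0, 548.0, 730.0, 912.0, 1095.0, 1277.0, 1460.0, 1642.0, 1825.0]
)


def make_obs(implant, family, params, times=QUARTERLY, rate_times=(), jitter=None):
    q = cumulative_release(family, params, times)
    if jitter is not None:
        q = np.clip(q + jitter, 0.0, implant.dose_loaded)
    kwargs = {}
    if len(rate_times):
        from implantpk import release_rate

        kwargs = {
            "rate_t": np.asarray(rate_times, dtype=float),
            "rate_r": release_rate(family, params, np.asarray(rate_times, dtype=float)),
        }
    return ObservationSet(implant=implant, amount_t=times, amount_q=q, **kwargs)


class TestObjective:
    def test_perfect_fit_is_zero(self, jadelle, first_order_params):
        obs = make_obs(jadelle, "first_order", first_order_params)
        assert objective_sse("first_order", first_order_params, obs, rate_weight=7.0) == 0.0

    def test_single_point_residual(self, jadelle, first_order_params):
        q365 = cumulative_release("first_order", first_order_params, 365.0)
        obs = ObservationSet(implant=jadelle, amount_t=[365.0], amount_q=[20.0])
        sse = objective_sse("first_order", first_order_params, obs, rate_weight=0.0)
        assert sse == pytest.approx((20.0 - q365) ** 2, rel=1e-12)
        assert sse == pytest.approx(0.999, abs=2e-3)

    def test_rate_only_with_zero_weight(self, jadelle):
        obs = ObservationSet(implant=jadelle, rate_t=[30.0], rate_r=[0.1])
        assert objective_sse("first_order", FIRST_ORDER_TRUTH, obs, rate_weight=0.0) == 0.0

    def test_invalid_parameters_give_infinity(self, jadelle, first_order_params):
        obs = make_obs(jadelle, "first_order", first_order_params)
        assert objective_sse("first_order", {"Qmax": -5.0, "k1": 0.0009}, obs) == np.inf

    def test_invariant_under_reordering(self, jadelle, first_order_params):
        rng = np.random.default_rng(0)
        times = QUARTERLY[1:]
        obs1 = make_obs(jadelle, "first_order", first_order_params, times,
                        jitter=rng.normal(0, 1, times.size))
        perm = rng.permutation(times.size)
        obs2 = ObservationSet(
            implant=jadelle, amount_t=obs1.amount_t[perm], amount_q=obs1.amount_q[perm]
        )
        trial = {"Qmax": 60.0, "k1": 0.001}
        assert objective_sse("first_order", trial, obs1) == pytest.approx(
            objective_sse("first_order", trial, obs2), rel=1e-14
        )

    def test_empty_observations_rejected(self, jadelle):
        obs = ObservationSet(implant=jadelle)
        with pytest.raises(ValueError, match="empty"):
            objective_sse("first_order", FIRST_ORDER_TRUTH, obs)


class TestFitting:
    @pytest.mark.parametrize("family,truth", FAMILY_TRUTHS.items())
    def test_noise_free_recovery(self, jadelle, family, truth):
        """Every family refits its own noise-free data essentially exactly."""
        simple = {"first_order", "zero_order", "higuchi"}
        tol = 1e-3 if family in simple else 1e-2
        rate_times = (30.44, 365.28, 730.56) if family == "biexponential" else ()
        obs = make_obs(jadelle, family, truth, rate_times=rate_times)
        fixed = {"Dose": 150.0} if family == "biexponential" else {}
        fit = fit_release_model(obs, family, FitOptions(fixed=fixed))
        assert fit.converged
        assert fit.sse < 1e-6
        for name, value in truth.items():
            if name in fixed:
                continue
            assert fit.estimates[name] == pytest.approx(value, rel=tol)

    def test_zero_order_matches_analytic_regression_through_origin(self, jadelle):
        """The fitted slope equals the closed-form OLS slope Σtq/Σt²."""
        rng = np.random.default_rng(42)
        t = np.array([100.0, 400.0, 800.0, 1200.0, 1825.0])
        q = 0.03 * t + rng.normal(0.0, 1.0, t.size)
        obs = ObservationSet(implant=jadelle, amount_t=t, amount_q=np.clip(q, 0, 150))
        fit = fit_release_model(obs, "zero_order")
        slope = float(np.sum(t * obs.amount_q) / np.sum(t**2))
        assert fit.estimates["k"] == pytest.approx(slope, rel=1e-8)
        # closed-form regression-through-origin CI
        resid = obs.amount_q - slope * t
        s2 = float(resid @ resid) / (t.size - 1)
        se = np.sqrt(s2 / np.sum(t**2))
        tq = stats.t.ppf(0.975, t.size - 1)
        lo, hi = fit.ci["k"]
        assert (lo, hi) == pytest.approx((slope - tq * se, slope + tq * se), rel=1e-6)

    def test_refit_from_optimum_is_idempotent(self, jadelle, first_order_params):
        rng = np.random.default_rng(7)
        obs = make_obs(jadelle, "first_order", first_order_params,
                       jitter=rng.normal(0, 2, QUARTERLY.size))
        fit1 = fit_release_model(obs, "first_order")
        fit2 = fit_release_model(
            obs, "first_order", FitOptions(starting_values=dict(fit1.estimates.values))
        )
        assert fit2.sse == pytest.approx(fit1.sse, abs=1e-8)

    def test_deterministic_for_identical_inputs(self, jadelle, first_order_params):
        obs = make_obs(jadelle, "first_order", first_order_params)
        f1 = fit_release_model(obs, "first_order")
        f2 = fit_release_model(obs, "first_order")
        assert dict(f1.estimates.values) == dict(f2.estimates.values)

    def test_insufficient_data_is_an_error(self, jadelle):
        obs = ObservationSet(implant=jadelle, amount_t=[365.0, 730.0], amount_q=[20.0, 35.0])
        with pytest.raises(ValueError, match="observations"):
            fit_release_model(obs, "first_order")

    def test_sigma2_is_unbiased_under_gaussian_noise(self, jadelle):
        """E[SSE/df] ≈ σ² across replicates (Monte-Carlo tolerance)."""
        sigma = 1.5
        t = QUARTERLY[1:]
        est = []
        for rep in range(200):
            rng = np.random.default_rng(rep)
            obs = make_obs(jadelle, "zero_order", {"k": 0.03}, t,
                           jitter=rng.normal(0, sigma, t.size))
            est.append(fit_release_model(obs, "zero_order").sigma2)
        assert np.mean(est) == pytest.approx(sigma**2, rel=0.15)

    def test_joint_rate_and_amount_fit_reports_weight(self, jadelle, biexp_params):
        cfg = SyntheticConfig(
            family="biexponential", params=biexp_params, implant=jadelle,
            additive_sd=0.0, seed=0,
        )
        amounts = generate_ex_vivo(cfg)
        rates = generate_label_rates(cfg)
        obs = ObservationSet(
            implant=jadelle,
            amount_t=amounts.amount_t, amount_q=amounts.amount_q,
            rate_t=[r.t for r in rates], rate_r=[r.rate for r in rates],
        )
        fit = fit_release_model(obs, "biexponential", FitOptions(fixed={"Dose": 150.0}))
        mean_q = np.mean(obs.amount_q)
        mean_r = np.mean(obs.rate_r)
        assert fit.rate_weight_used == pytest.approx((mean_q / mean_r) ** 2)
        assert fit.n_obs == 16


class TestGoodnessOfFit:
    def test_perfect_fit_gives_unity(self):
        assert adjusted_r_squared(0.0, 100.0, 13, 2) == pytest.approx(1.0)

    def test_worked_arithmetic(self):
        # R² = 0.9, n = 10, p = 2 → 1 − 0.1·9/7
        assert adjusted_r_squared(10.0, 100.0, 10, 2) == pytest.approx(1 - 0.1 * 9 / 7)
        assert adjusted_r_squared(10.0, 100.0, 10, 2) == pytest.approx(0.8714, abs=1e-4)

    def test_zero_parameters_collapse_to_r2(self):
        assert adjusted_r_squared(25.0, 100.0, 10, 0) == pytest.approx(0.75)

    def test_degenerate_dof_rejected(self):
        with pytest.raises(ValueError):
            adjusted_r_squared(1.0, 10.0, 4, 3)
        with pytest.raises(ValueError):
            adjusted_r_squared(1.0, 0.0, 10, 2)

    def test_adjusted_never_exceeds_r2(self, jadelle, first_order_params):
        rng = np.random.default_rng(3)
        obs = make_obs(jadelle, "first_order", first_order_params,
                       jitter=rng.normal(0, 2, QUARTERLY.size))
        fit = fit_release_model(obs, "first_order")
        assert fit.adjusted_r2 <= fit.r2
        # brute-force recomputation from raw residuals
        resid = obs.amount_q - cumulative_release("first_order", fit.estimates, obs.amount_t)
        sse = float(resid @ resid)
        sst = float(np.sum((obs.amount_q - obs.amount_q.mean()) ** 2))
        n, p = obs.n_obs, 2
        expected = 1 - (1 - (1 - sse / sst)) * (n - 1) / (n - p - 1)
        assert fit.adjusted_r2 == pytest.approx(expected, rel=1e-10)


class TestIntervals:
    def test_zero_residual_fit_has_zero_width_intervals(self, jadelle, first_order_params):
        obs = make_obs(jadelle, "first_order", first_order_params)
        fit = fit_release_model(obs, "first_order")
        for lo, hi in fit.ci.values():
            assert hi - lo == pytest.approx(0.0, abs=1e-8)

    def test_intervals_bracket_estimates(self, jadelle, first_order_params):
        rng = np.random.default_rng(11)
        obs = make_obs(jadelle, "first_order", first_order_params,
                       jitter=rng.normal(0, 2, QUARTERLY.size))
        fit = fit_release_model(obs, "first_order")
        cis = parameter_cis(fit, 0.95)
        for name, (lo, hi) in cis.items():
            assert lo <= fit.estimates[name] <= hi
        wide = parameter_cis(fit, 0.99)
        for name in cis:
            assert wide[name][1] - wide[name][0] >= cis[name][1] - cis[name][0]

    def test_poorly_identified_biexponential_ci_may_span_zero(self, jadelle, biexp_params):
        """Sparse data: the fast-phase amplitude interval can include negatives."""
        rng = np.random.default_rng(5)
        times = np.array([91.0, 365.0, 730.0, 1095.0, 1460.0, 1825.0])
        obs = make_obs(jadelle, "biexponential", biexp_params, times,
                       jitter=rng.normal(0, 3.0, times.size))
        fit = fit_release_model(obs, "biexponential", FitOptions(fixed={"Dose": 150.0}))
        lo, _hi = fit.ci["Qb1"]
        assert lo < 0  # permitted and reported, not suppressed

    def test_band_contains_point_prediction_and_widens_when_extrapolating(
        self, jadelle, first_order_params
    ):
        rng = np.random.default_rng(2)
        obs = make_obs(jadelle, "first_order", first_order_params,
                       jitter=rng.normal(0, 2, QUARTERLY.size))
        fit = fit_release_model(obs, "first_order")
        band = prediction_band(fit, [900.0, 3000.0], 0.95)
        assert (band["lower"] <= band["predicted"]).all()
        assert (band["predicted"] <= band["upper"]).all()
        half = (band["upper"] - band["lower"]) / 2
        assert half.iloc[1] > half.iloc[0]

    def test_band_coverage_of_true_curve(self, jadelle, first_order_params):
        """≈95% of noisy replicates keep the true curve inside the band
        at an interior time (Monte-Carlo check)."""
        t_check = 900.0
        truth_q = cumulative_release("first_order", first_order_params, t_check)
        inside = 0
        n_rep = 300
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            obs = make_obs(jadelle, "first_order", first_order_params, QUARTERLY[1:],
                           jitter=rng.normal(0, 2, QUARTERLY.size - 1))
            fit = fit_release_model(obs, "first_order")
            band = prediction_band(fit, [t_check], 0.95)
            inside += band["lower"].iloc[0] <= truth_q <= band["upper"].iloc[0]
        assert inside / n_rep > 0.93  # band also covers observation noise


class TestModelComparison:
    def _dummy_fit(self, base, family_id, adj, n_params, converged=True):
        return dataclasses.replace(
            base,
            family_id=family_id,
            adjusted_r2=adj,
            n_params=n_params,
            converged=converged,
        )

    @pytest.fixture
    def base_fit(self, jadelle, first_order_params):
        obs = make_obs(jadelle, "first_order", first_order_params)
        return fit_release_model(obs, "first_order")

    def test_reported_ranking_order(self, base_fit):
        """Given the published adjusted R² values, the ranking is
        first-order > Hixson-Crowell > Korsmeyer-Peppas > Weibull > biexponential."""
        published = {
            "first_order": 0.9170,
            "hixson_crowell": 0.9157,
            "korsmeyer_peppas": 0.9133,
            "weibull": 0.9130,
            "biexponential": 0.9113,
        }
        fits = [
            self._dummy_fit(base_fit, fam, adj, n)
            for (fam, adj), n in zip(published.items(), [2, 2, 2, 3, 3])
        ]
        order = compare_models(fits[::-1])["family_id"].tolist()
        assert order == list(published)

    def test_single_fit_ranks_itself(self, base_fit):
        assert compare_models([base_fit])["family_id"].tolist() == ["first_order"]

    def test_tie_broken_by_fewer_parameters(self, base_fit):
        a = self._dummy_fit(base_fit, "weibull", 0.91, 3)
        b = self._dummy_fit(base_fit, "first_order", 0.91, 2)
        assert compare_models([a, b])["family_id"].tolist() == ["first_order", "weibull"]

    def test_non_converged_fits_rank_last(self, base_fit):
        good = self._dummy_fit(base_fit, "first_order", 0.5, 2)
        bad = self._dummy_fit(base_fit, "weibull", 0.99, 3, converged=False)
        table = compare_models([bad, good])
        assert table["family_id"].tolist() == ["first_order", "weibull"]
        assert not table.iloc[1]["converged"]

    def test_mixed_datasets_rejected(self, base_fit, jadelle, first_order_params):
        other_obs = make_obs(jadelle, "first_order", first_order_params, QUARTERLY[1:])
        other = fit_release_model(other_obs, "first_order")
        with pytest.raises(ValueError, match="different observation sets"):
            compare_models([base_fit, other])
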