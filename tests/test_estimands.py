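"""HTA estimands: points, percentile intervals, and population truth."""

import numpy as np
import pytest

from parsurvsim import (
    ScenarioConfig,
    compute_estimands,
    fit_mle,
    generate_population,
    interval_estimands,
    population_truth,
    scenario_preset,
)
from parsurvsim.estimands import draw_parameters
from parsurvsim.fitting import FittedModel
from parsurvsim.families import exponential, get_family

TH_POP = 1842.0681


def _exp_model(rate=0.0025, d=100):
    return FittedModel(
        family=exponential,
        params=np.array([rate]),
        theta=np.array([np.log(rate)]),
        cov=np.array([[1.0 / d]]),
        loglik=-1.0,
        converged=True,
        reason="",
        n_subjects=d,
        n_events=d,
    )


class TestPointEstimands:
    def test_exponential_closed_forms(self):
        est = compute_estimands(_exp_model(), TH_POP)
        assert est.point["median"] == pytest.approx(277.26, abs=0.01)
        assert est.point["s365"] == pytest.approx(0.40152, abs=1e-4)
        assert est.point["th"] == pytest.approx(1842.07, abs=0.01)
        assert est.point["rmst_pop_th"] == pytest.approx(396.0, abs=1e-3)
        # at the truth the own horizon coincides with the population horizon
        assert est.point["rmst_sample_th"] == pytest.approx(
            est.point["rmst_pop_th"], abs=1e-6
        )

    def test_low_rate_median(self):
        est = compute_estimands(_exp_model(rate=0.00075), TH_POP)
        assert est.point["median"] == pytest.approx(924.2, abs=0.1)

    def test_infinite_horizon_propagates(self):
        fam = get_family("gompertz")
        params = np.array([-0.01, 0.001])
        m = FittedModel(
            family=fam, params=params,
            theta=fam.to_unconstrained(params),
            cov=np.eye(2) * 1e-6, loglik=-1.0, converged=True, reason="",
            n_subjects=50, n_events=40,
        )
        est = compute_estimands(m, TH_POP)
        assert np.isinf(est.point["th"])
        assert np.isinf(est.point["rmst_sample_th"])
        assert np.isfinite(est.point["rmst_pop_th"])

    def test_requires_finite_population_horizon(self):
        with pytest.raises(ValueError):
            compute_estimands(_exp_model(), np.inf)


class TestIntervalEstimands:
    def test_degenerate_covariance_gives_point_intervals(self, rng):
        m = _exp_model()
        m.cov = np.array([[1e-18]])
        est = interval_estimands(m, TH_POP, b=500, rng=rng)
        for name in ("median", "s365", "th", "rmst_pop_th"):
            assert est.lo[name] == pytest.approx(est.point[name], rel=1e-3)
            assert est.hi[name] == pytest.approx(est.point[name], rel=1e-3)

    def test_exponential_median_ci_is_transformed_rate_ci(self, rng):
        """Monotone transform: median bounds = ln2 / (rate bounds reversed)."""
        m = _exp_model(d=50)
        draws = draw_parameters(m, 4000, np.random.default_rng(1))
        est = interval_estimands(
            m, TH_POP, b=4000, rng=np.random.default_rng(1)
        )
        rate_lo, rate_hi = np.percentile(draws[:, 0], [2.5, 97.5])
        # linear percentile interpolation commutes with the monotone
        # transform only approximately
        assert est.lo["median"] == pytest.approx(np.log(2) / rate_hi, rel=1e-5)
        assert est.hi["median"] == pytest.approx(np.log(2) / rate_lo, rel=1e-5)

    def test_sampling_ci_matches_delta_method_width(self, rng):
        """Oracle cross-check at n=120: lognormal-delta CI for the rate."""
        d = 120
        m = _exp_model(d=d)
        est = interval_estimands(m, TH_POP, b=20_000, rng=rng)
        z = 1.959964
        se = np.sqrt(1.0 / d)
        delta_lo = np.log(2) / (m.params[0] * np.exp(z * se))
        delta_hi = np.log(2) / (m.params[0] * np.exp(-z * se))
        width_ratio = (est.hi["median"] - est.lo["median"]) / (
            delta_hi - delta_lo
        )
        assert width_ratio == pytest.approx(1.0, abs=0.05)

    def test_doubling_draws_is_stable(self):
        m = _exp_model(d=200)
        a = interval_estimands(m, TH_POP, b=4000, rng=np.random.default_rng(5))
        b = interval_estimands(m, TH_POP, b=8000, rng=np.random.default_rng(6))
        assert a.lo["median"] == pytest.approx(b.lo["median"], rel=0.02)
        assert a.hi["median"] == pytest.approx(b.hi["median"], rel=0.02)

    def test_minimum_draw_count_enforced(self, rng):
        with pytest.raises(ValueError):
            interval_estimands(_exp_model(), TH_POP, b=50, rng=rng)

    def test_missing_covariance_marks_failure(self, rng):
        m = _exp_model()
        m.cov = None
        est = interval_estimands(m, TH_POP, rng=rng)
        assert est.ci_failure
        assert np.isfinite(est.point["median"])


class TestPopulationTruth:
    def test_theoretical_closed_forms(self):
        cfg = scenario_preset(1)
        truth = population_truth(cfg, source="theoretical")
        assert truth.median == pytest.approx(277.2589, abs=1e-3)
        assert truth.th == pytest.approx(1842.068, abs=1e-2)
        assert truth.rmst_pop_th == pytest.approx(396.0, abs=1e-6)
        low = population_truth(
            scenario_preset(3), source="theoretical"
        )
        assert low.median == pytest.approx(924.196, abs=1e-2)

    def test_population_fit_close_to_theory(self, scenario1_population):
        cfg = scenario_preset(1, seed=123)
        fit_truth = population_truth(
            cfg, scenario1_population, source="population_fit"
        )
        theory = population_truth(cfg, source="theoretical")
        # MLE sampling error of the rate is ~ rate/sqrt(50000) ~ 0.45%
        assert fit_truth.median == pytest.approx(theory.median, rel=0.015)
        assert fit_truth.rmst_pop_th == pytest.approx(
            theory.rmst_pop_th, rel=0.015
        )

    def test_population_fit_requires_population(self):
        with pytest.raises(ValueError):
            population_truth(scenario_preset(1), source="population_fit")

    def test_rmst_at_truth_quadrature_matches_closed_form(self):
        """Generic quadrature against the exponential closed form."""
        from parsurvsim.families import weibull

        rate = 0.0025
        th = -np.log(0.01) / rate
        quad = weibull.rmst(np.array([1.0, 1.0 / rate]), th)
        assert quad == pytest.approx(0.99 / rate, abs=1e-6)
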