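"""Right-censored maximum likelihood and information criteria."""

import numpy as np
import pytest
from scipy import optimize

from parsurvsim import fit_mle, get_family, information_criteria, log_likelihood
from parsurvsim.families import FAMILY_ORDER, exponential


class TestLogLikelihood:
    def test_exponential_closed_form_value(self):
        # d ln(rate) - rate * sum(t) with three events
        ll = log_likelihood(exponential, [0.005], [100, 200, 300], [1, 1, 1])
        assert ll == pytest.approx(3 * np.log(0.005) - 3.0, abs=1e-12)
        assert ll == pytest.approx(-18.895, abs=1e-3)

    def test_all_censored_has_no_density_terms(self):
        ll = log_likelihood(exponential, [0.004], [50, 70], [0, 0])
        assert ll == pytest.approx(-0.004 * 120)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood(exponential, [0.01], [0.0, 5.0], [1, 1])

    def test_mle_dominates_perturbations(self, censored_sample):
        times, events = censored_sample
        m = fit_mle("weibull", times, events)
        for delta in ([0.05, 0], [-0.05, 0], [0, 30], [0, -30]):
            assert (
                log_likelihood(m.family, m.params + delta, times, events)
                <= m.loglik + 1e-9
            )


class TestExponentialMle:
    def test_closed_form_examples(self):
        m = fit_mle("exponential", [100, 200, 300], [1, 1, 0])
        assert m.params[0] == pytest.approx(2 / 600)
        m = fit_mle("exponential", [100, 200, 300], [1, 1, 1])
        assert m.params[0] == pytest.approx(0.005)
        assert m.loglik == pytest.approx(-18.895, abs=1e-3)

    def test_matches_brute_force_optimizer_on_random_data(self):
        """Oracle: independent numeric optimization of the likelihood."""
        r = np.random.default_rng(0)
        for _ in range(100):
            n = int(r.integers(5, 200))
            t = r.exponential(r.uniform(100, 800), n)
            cut = np.quantile(t, r.uniform(0.3, 1.0))
            e = (t <= cut).astype(int)
            if e.sum() == 0:
                continue
            times = np.where(e == 1, t, cut)
            m = fit_mle("exponential", times, e)
            brute = optimize.minimize_scalar(
                lambda lograte: -log_likelihood(
                    exponential, [np.exp(lograte)], times, e
                ),
                bounds=(-12, 0),
                method="bounded",
                options={"xatol": 1e-12},
            )
            assert m.params[0] == pytest.approx(np.exp(brute.x), rel=1e-6)
            assert m.params[0] == pytest.approx(e.sum() / times.sum(), rel=1e-12)

    def test_zero_events_flagged_not_raised(self):
        m = fit_mle("exponential", [10.0, 20.0], [0, 0])
        assert not m.converged
        assert m.reason == "no_events"


class TestNumericMle:
    @pytest.mark.parametrize("name", ["weibull", "lognormal", "loglogistic"])
    def test_agrees_with_lifelines(self, name, censored_sample):
        """Independent fitting oracle on the same censored data."""
        import lifelines

        times, events = censored_sample
        m = fit_mle(name, times, events)
        fitter = {
            "weibull": lifelines.WeibullFitter,
            "lognormal": lifelines.LogNormalFitter,
            "loglogistic": lifelines.LogLogisticFitter,
        }[name]().fit(times, events)
        assert m.loglik == pytest.approx(fitter.log_likelihood_, rel=1e-6)
        ours = {
            "weibull": [m.params[1], m.params[0]],  # scale, shape
            "lognormal": list(m.params),
            "loglogistic": [m.params[1], m.params[0]],
        }[name]
        theirs = list(fitter._fitted_parameter_names)
        vals = [getattr(fitter, p) for p in theirs]
        assert np.allclose(ours, vals, rtol=1e-4)

    @pytest.mark.parametrize(
        "name", ["exponential", "weibull", "gengamma", "gompertz"]
    )
    def test_large_sample_median_recovery_nested_families(self, name):
        """Families nesting the exponential recover its median at large n."""
        r = np.random.default_rng(3)
        t = r.exponential(400.0, 50_000)
        m = fit_mle(name, t, np.ones_like(t, dtype=int))
        assert m.converged
        med = float(np.asarray(m.family.quantile(0.5, m.params)))
        assert med == pytest.approx(277.26, rel=0.02)

    @pytest.mark.parametrize("name", ["lognormal", "loglogistic"])
    def test_misspecified_families_lose_to_truth_at_large_n(self, name):
        """Non-nesting families converge but fit strictly worse than the
        generating exponential (their pseudo-true median is biased)."""
        r = np.random.default_rng(3)
        t = r.exponential(400.0, 50_000)
        e = np.ones_like(t, dtype=int)
        m = fit_mle(name, t, e)
        m_exp = fit_mle("exponential", t, e)
        assert m.converged
        assert m.loglik < m_exp.loglik
        med = float(np.asarray(m.family.quantile(0.5, m.params)))
        assert 150 < med < 350  # biased but in a sane range

    def test_covariance_is_positive_definite(self, censored_sample):
        times, events = censored_sample
        for name in FAMILY_ORDER:
            m = fit_mle(name, times, events)
            assert m.converged, name
            np.linalg.cholesky(m.cov)  # raises if not PD

    def test_ic_ranking_invariant_to_time_rescaling(self, censored_sample):
        """Days -> months shifts every loglik by n_ev*ln(30); ranks survive."""
        times, events = censored_sample
        aic_days = {}
        aic_months = {}
        for name in FAMILY_ORDER:
            aic_days[name] = fit_mle(name, times, events).aic
            aic_months[name] = fit_mle(name, times / 30.0, events).aic
        rank = lambda d: sorted(d, key=d.get)
        assert rank(aic_days) == rank(aic_months)


class TestInformationCriteria:
    def test_textbook_values(self):
        m = fit_mle("exponential", [100, 200, 300], [1, 1, 1])
        assert m.aic == pytest.approx(39.790, abs=1e-3)
        assert m.bic == pytest.approx(38.888, abs=1e-3)

    def test_small_sample_corrections_vanish_with_n(self):
        r = np.random.default_rng(1)
        t = r.exponential(400, 5000)
        m = fit_mle("exponential", t, np.ones_like(t, dtype=int))
        assert m.aicc == pytest.approx(m.aic, abs=1e-2)
        assert m.bicc == pytest.approx(m.bic, abs=1e-2)

    def test_undefined_when_n_too_small(self):
        # generalized gamma has k=3; n=4 leaves no room for the correction
        m = fit_mle("exponential", [50.0, 60.0], [1, 1])
        aic, bic, aicc, bicc = information_criteria(m)
        assert np.isfinite(aic) and np.isfinite(bic)
        m2 = fit_mle("exponential", [50.0], [1])
        assert np.isnan(m2.aicc) and np.isnan(m2.bicc)

    def test_events_convention_available(self, censored_sample):
        times, events = censored_sample
        m_subj = fit_mle("weibull", times, events, ic_n="subjects")
        m_ev = fit_mle("weibull", times, events, ic_n="events")
        assert m_ev.bic == pytest.approx(
            -2 * m_ev.loglik + 2 * np.log(events.sum())
        )
        assert m_subj.bic > m_ev.bic  # fewer events than subjects

    def test_requires_convergence(self):
        m = fit_mle("exponential", [10.0], [0])
        with pytest.raises(ValueError):
            information_criteria(m)

    def test_serializable_row(self, censored_sample):
        times, events = censored_sample
        row = fit_mle("gengamma", times, events).to_row()
        assert row["family"] == "gengamma"
        assert row["k"] == 3
        assert len(row["params"].split(";")) == 3
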