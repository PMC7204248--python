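"""Standard parametric families: likelihood, MLE, survival and RMST."""

import numpy as np
import pytest

import survcuts as sc
from survcuts import families
from survcuts.families import ParameterDomainError
from survcuts.parametric import FitError

from conftest import make_censored_dataset

UNCENSORED_1234 = sc.SurvivalDataset((1, 2, 3, 4), (1, 1, 1, 1))


class TestLoglik:
    def test_exponential_closed_form(self):
        # 4 log(0.4) - 0.4 * 10
        assert sc.loglik("exponential", [0.4], UNCENSORED_1234) == pytest.approx(
            4 * np.log(0.4) - 4.0, abs=1e-10
        )

    @pytest.mark.parametrize("family,params", [
        ("exponential", [0.2]),
        ("weibull", [1.4, 8.0]),
        ("gompertz", [0.05, 0.02]),
        ("lognormal", [1.5, 0.9]),
        ("loglogistic", [2.0, 9.0]),
        ("gengamma", [1.8, 0.7, 0.5]),
    ])
    def test_early_censored_contribution_vanishes(self, family, params):
        tiny = sc.SurvivalDataset((1e-10,), (0,))
        assert sc.loglik(family, params, tiny) == pytest.approx(0.0, abs=1e-6)

    def test_weibull_shape_one_nests_exponential(self, sim_dataset):
        rate = 0.11
        ll_w = sc.loglik("weibull", [1.0, 1.0 / rate], sim_dataset)
        ll_e = sc.loglik("exponential", [rate], sim_dataset)
        assert ll_w == pytest.approx(ll_e, abs=1e-9)

    def test_domain_errors(self, sim_dataset):
        with pytest.raises(ParameterDomainError):
            sc.loglik("weibull", [-1.0, 5.0], sim_dataset)
        with pytest.raises(ParameterDomainError):
            sc.loglik("lognormal", [1.0, 0.0], sim_dataset)


class TestFitMle:
    def test_exponential_analytic_mle(self):
        m = sc.fit_mle("exponential", UNCENSORED_1234)
        assert m.params[0] == pytest.approx(0.4, rel=1e-6)
        assert m.k == 1 and m.n == 4 and m.converged

    def test_zero_events_raises(self):
        with pytest.raises(FitError):
            sc.fit_mle("weibull", sc.SurvivalDataset((1, 2), (0, 0)))

    def test_nesting_inequalities(self):
        rng = np.random.default_rng(314)
        for _ in range(3):
            ds = make_censored_dataset(rng, n=120)
            ll = {f: sc.fit_mle(f, ds).loglik for f in
                  ("exponential", "weibull", "lognormal", "gengamma")}
            assert ll["weibull"] >= ll["exponential"] - 1e-6
            assert ll["gengamma"] >= ll["weibull"] - 1e-4
            assert ll["gengamma"] >= ll["lognormal"] - 1e-4

    def test_reference_library_agreement(self):
        """Maximized log-likelihoods match lifelines on fixed simulated data."""
        import lifelines

        fitters = {
            "exponential": lifelines.ExponentialFitter,
            "weibull": lifelines.WeibullFitter,
            "lognormal": lifelines.LogNormalFitter,
            "loglogistic": lifelines.LogLogisticFitter,
        }
        rng = np.random.default_rng(42)
        for i in range(20):
            ds = make_censored_dataset(rng, n=150)
            for fam, cls in fitters.items():
                ref = cls().fit(ds.times_array(), ds.events_array()).log_likelihood_
                m = sc.fit_mle(fam, ds)
                assert m.loglik == pytest.approx(ref, abs=1e-4), (i, fam)

    def test_gengamma_at_least_as_good_as_reference(self):
        from lifelines import GeneralizedGammaFitter

        rng = np.random.default_rng(43)
        for _ in range(5):
            ds = make_censored_dataset(rng, n=150)
            try:
                ref = GeneralizedGammaFitter().fit(
                    ds.times_array(), ds.events_array()
                ).log_likelihood_
            except Exception:
                continue
            assert sc.fit_mle("gengamma", ds).loglik >= ref - 1e-4

    def test_local_maximum_property(self):
        """Fitted params beat 64 random perturbations, every family, 20 datasets."""
        rng = np.random.default_rng(99)
        datasets = [make_censored_dataset(rng, n=80) for _ in range(20)]
        for family in families.FAMILIES:
            for ds in datasets:
                m = sc.fit_mle(family, ds)
                p = np.asarray(m.params)
                for _ in range(64):
                    q = p * np.exp(rng.normal(scale=0.05, size=p.size))
                    if family in ("lognormal", "gengamma"):
                        q[0] = p[0] + rng.normal(scale=0.05)
                    if family == "gengamma":
                        q[2] = p[2] + rng.normal(scale=0.05)
                    if family == "gompertz":
                        q[0] = p[0] + rng.normal(scale=0.01)
                    try:
                        ll = sc.loglik(family, q, ds)
                    except ParameterDomainError:
                        continue
                    assert ll <= m.loglik + 1e-6, (family, ds.label)


class TestModelSurvivalAndRmst:
    def test_exponential_closed_form_survival(self):
        m = sc.FittedModel("exponential", (0.1,), 1, -1.0, 10)
        assert sc.model_survival(m, 10.0) == pytest.approx(np.exp(-1.0))
        assert sc.model_survival(m, 0.0) == 1.0

    @pytest.mark.parametrize("family,params", [
        ("weibull", (1.3, 9.0)),
        ("gompertz", (0.06, 0.02)),
        ("lognormal", (1.8, 0.8)),
        ("loglogistic", (2.2, 8.0)),
        ("gengamma", (1.8, 0.8, 0.7)),
    ])
    def test_survival_normalized_monotone_vanishing(self, family, params):
        m = sc.FittedModel(family, params, len(params), -1.0, 10)
        grid = np.linspace(0.0, 400.0, 300)
        s = np.array([sc.model_survival(m, float(t)) for t in grid])
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)
        assert s[-1] < 1e-3

    def test_negative_gompertz_shape_has_plateau(self):
        m = sc.FittedModel("gompertz", (-0.05, 0.03), 2, -1.0, 10)
        plateau = np.exp(0.03 / -0.05)
        assert sc.model_survival(m, 1e4) == pytest.approx(plateau, abs=1e-9)
        assert np.isfinite(sc.model_rmst(m, 60.0))

    def test_gengamma_lognormal_limit(self):
        t = np.linspace(0.5, 60, 40)
        s_ln = families.sf("lognormal", (1.8, 0.8), t)
        for q in (0.0, 1e-6):
            s_gg = families.sf("gengamma", (1.8, 0.8, q), t)
            np.testing.assert_allclose(s_gg, s_ln, atol=1e-6)

    def test_gengamma_weibull_special_case(self):
        # Q = 1, sigma = 1/shape, mu = log(scale)
        shape, scale = 1.4, 9.0
        t = np.linspace(0.5, 50, 30)
        np.testing.assert_allclose(
            families.sf("gengamma", (np.log(scale), 1 / shape, 1.0), t),
            families.sf("weibull", (shape, scale), t),
            atol=1e-10,
        )

    def test_rmst_exponential_closed_form(self):
        m = sc.FittedModel("exponential", (0.1,), 1, -1.0, 10)
        expected = (1 - np.exp(-0.1 * 36)) / 0.1  # = 9.7268
        assert sc.model_rmst(m, 36.0) == pytest.approx(expected, abs=1e-6)
        assert sc.model_rmst(m, 0.0) == 0.0

    def test_rmst_bounded_by_tau(self, sim_dataset):
        for fam in ("weibull", "lognormal"):
            m = sc.fit_mle(fam, sim_dataset)
            assert sc.model_rmst(m, 24.0) <= 24.0
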