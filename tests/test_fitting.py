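"""Likelihoods, MLE quality, information criteria, and fit diagnostics."""

import io

import numpy as np
import pytest
from scipy import optimize, stats

from bmdbatch import (
    DoseResponseDataset,
    DoseResponseModel,
    fit_mle,
    gof_dichotomous,
    loglik_continuous,
    loglik_dichotomous,
    read_datasets,
)
from bmdbatch import tests_continuous as continuous_lr_tests
from bmdbatch.fitting import (
    _loglik_full,
    continuous_anova,
    saturated_loglik_dichotomous,
)
from bmdbatch.models import Logistic, Multistage, Polynomial


def direct_binomial_ll(p, y, n):
    p = np.clip(np.asarray(p, float), 1e-8, 1 - 1e-8)
    return float(sum(yi * np.log(pi) + (ni - yi) * np.log(1 - pi)
                     for yi, ni, pi in zip(y, n, p)))


class TestDichotomousLoglik:
    def test_saturated_closed_form(self):
        ds = DoseResponseDataset("s", "dichotomous", [0, 10, 100], [10, 10, 10],
                                 incidence=[0, 5, 10])
        # y/n = 0, 0.5, 1: only the middle group contributes 10 ln(1/2)
        assert saturated_loglik_dichotomous(ds) == pytest.approx(10 * np.log(0.5), abs=1e-4)
        assert saturated_loglik_dichotomous(ds) == pytest.approx(-6.9315, abs=1e-3)

    def test_constant_half_probability(self):
        ds = DoseResponseDataset("s", "dichotomous", [0, 10], [10, 10],
                                 incidence=[5, 5])
        spec = Multistage(1)
        # gamma = 0.5, beta1 = 0 gives p = 0.5 everywhere
        ll = loglik_dichotomous(spec, [0.5, 0.0], ds)
        assert ll == pytest.approx(20 * np.log(0.5), rel=1e-10)
        assert ll == pytest.approx(-13.8629, abs=1e-3)

    def test_matches_direct_summation_oracle(self):
        ds = DoseResponseDataset("s", "dichotomous", [0, 10, 100], [10, 10, 10],
                                 incidence=[0, 2, 8])
        spec = Multistage(1)
        for params in ([0.01, 0.005], [0.1, 0.02], [0.0, 0.001]):
            p = spec.predict(np.asarray(params), ds.doses)
            assert loglik_dichotomous(spec, params, ds) == pytest.approx(
                direct_binomial_ll(p, ds.incidence, ds.n), rel=1e-12
            )


class TestContinuousLoglik:
    def test_single_group_closed_form(self):
        ds = DoseResponseDataset("s", "continuous", [0, 1], [2, 2],
                                 mean=[0.0, 0.0], sd=[np.sqrt(2), np.sqrt(2)])
        spec = Polynomial(1, variance_mode="constant")
        # mu = 0, sigma^2 = 1: per group LL = -ln(2 pi) - 1
        ll = loglik_continuous(spec, [0.0, 0.0], [np.log(1.0)], ds)
        assert ll == pytest.approx(2 * (-np.log(2 * np.pi) - 1.0), rel=1e-12)
        assert ll / 2 == pytest.approx(-2.8379, abs=1e-3)

    def test_modeled_variance_rho_zero_reduces_to_constant(self, cont_dataset):
        const = Polynomial(1, variance_mode="constant")
        modeled = Polynomial(1, variance_mode="modeled")
        mean_params = [100.0, 0.2]
        for s2 in (10.0, 150.0):
            ll_c = loglik_continuous(const, mean_params, [np.log(s2)], cont_dataset)
            ll_m = loglik_continuous(modeled, mean_params, [np.log(s2), 0.0], cont_dataset)
            assert ll_m == pytest.approx(ll_c, rel=1e-12)

    def test_saturated_means_match_direct_oracle(self, cont_dataset):
        an = continuous_anova(cont_dataset)
        n = cont_dataset.n.astype(float)
        s2 = cont_dataset.sd**2
        m = cont_dataset.mean

        def direct(mu, var):
            return float(np.sum(
                -(n / 2) * np.log(2 * np.pi * var)
                - ((n - 1) * s2 + n * (m - mu) ** 2) / (2 * var)
            ))

        # A1
        pooled = np.sum((n - 1) * s2) / np.sum(n)
        assert an["A1"][0] == pytest.approx(direct(m, np.full_like(m, pooled)), rel=1e-10)
        # A2
        gv = (n - 1) * s2 / n
        assert an["A2"][0] == pytest.approx(direct(m, gv), rel=1e-10)
        # R
        mu_r = np.sum(n * m) / np.sum(n)
        var_r = (np.sum((n - 1) * s2) + np.sum(n * (m - mu_r) ** 2)) / np.sum(n)
        assert an["R"][0] == pytest.approx(direct(np.full_like(m, mu_r), np.full_like(m, var_r)), rel=1e-10)
        # A3 by an independent 2-parameter optimization over (ln alpha, rho)
        absm = np.maximum(np.abs(m), 1e-8)

        def neg_a3(x):
            return -direct(m, np.exp(x[0]) * absm ** x[1])

        best = min(
            (optimize.minimize(neg_a3, x0, method="Nelder-Mead",
                               options={"fatol": 1e-12, "xatol": 1e-10}).fun
             for x0 in ([np.log(pooled), 0.0], [np.log(pooled), 2.0])),
        )
        assert an["A3"][0] == pytest.approx(-best, abs=1e-6)

    def test_a3_between_a1_and_a2(self, cont_dataset):
        an = continuous_anova(cont_dataset)
        assert an["A1"][0] - 1e-9 <= an["A3"][0] <= an["A2"][0] + 1e-9


class TestMle:
    def test_logistic_parameter_recovery_exact_data(self):
        true = np.array([-2.0, 0.03])
        spec = Logistic()
        doses = np.array([0.0, 20.0, 60.0, 120.0, 200.0])
        n = np.full(5, 100000)
        p = spec.predict(true, doses)
        ds = DoseResponseDataset("rec", "dichotomous", doses, n,
                                 incidence=np.round(n * p).astype(int))
        fit = fit_mle(spec, ds)
        assert fit.converged
        np.testing.assert_allclose(fit.params, true, rtol=0.01)

    def test_flat_response_gives_flat_curve(self):
        ds = DoseResponseDataset("flat", "dichotomous", [0, 10, 100], [10, 10, 10],
                                 incidence=[1, 1, 1])
        fit = fit_mle(Multistage(1), ds)
        p = fit.predicted
        assert np.ptp(p) < 0.02
        assert fit.bmd() is None or fit.bmd() > ds.max_dose

    def test_stochastic_optimality_audit(self, dich_dataset):
        fit = fit_mle(Multistage(2), dich_dataset)
        spec = fit.spec
        rng = np.random.default_rng(42)
        lo = np.array([0.0, 0.0, 0.0])
        hi = np.array([0.5, 0.1, 1e-3])
        for _ in range(1000):
            cand = rng.uniform(lo, hi)
            assert fit.loglik >= _loglik_full(spec, cand, dich_dataset) - 1e-9

    def test_aic_identity(self, dich_dataset, cont_dataset):
        for ds, spec in [(dich_dataset, Multistage(2)),
                         (cont_dataset, Polynomial(1, variance_mode="modeled"))]:
            fit = fit_mle(spec, ds)
            assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * len(fit.params), rel=1e-14)

    def test_nested_models_never_worse_when_richer(self, dich_dataset):
        ll1 = fit_mle(Multistage(1), dich_dataset).loglik
        ll2 = fit_mle(Multistage(2), dich_dataset).loglik
        assert ll2 >= ll1 - 1e-6

    def test_nested_polynomials(self, cont_dataset):
        ll1 = fit_mle(Polynomial(1), cont_dataset).loglik
        ll2 = fit_mle(Polynomial(2), cont_dataset).loglik
        assert ll2 >= ll1 - 1e-6

    def test_saturated_is_upper_bound(self, dich_dataset, cont_dataset):
        sat_d = saturated_loglik_dichotomous(dich_dataset)
        for spec in (Multistage(4), Logistic()):
            assert fit_mle(spec, dich_dataset).loglik <= sat_d + 1e-6
        sat_c = continuous_anova(cont_dataset)["A2"][0]
        assert fit_mle(Polynomial(2), cont_dataset).loglik <= sat_c + 1e-6

    def test_row_order_in_csv_does_not_change_fit(self):
        fwd = "dataset_id,dose,n,incidence\nA,0,50,2\nA,10,50,9\nA,40,50,20\nA,100,50,36\n"
        rows = fwd.strip().split("\n")
        rev = "\n".join([rows[0]] + rows[1:][::-1])
        (ds1,) = read_datasets(io.StringIO(fwd), "dichotomous")
        (ds2,) = read_datasets(io.StringIO(rev), "dichotomous")
        f1 = fit_mle(Multistage(2), ds1)
        f2 = fit_mle(Multistage(2), ds2)
        np.testing.assert_array_equal(f1.params, f2.params)

    def test_from_dataframe(self, dich_dataset):
        model = DoseResponseModel.from_dataframe(
            dich_dataset.to_frame(), Multistage(2), dataset_id="df-1"
        )
        fit = model.fit()
        assert fit.converged
        assert fit.dataset.dataset_id == "df-1"


class TestGof:
    def test_perfect_fit_p_one(self):
        ds = DoseResponseDataset("g", "dichotomous", [0, 10, 100], [10, 10, 10],
                                 incidence=[1, 2, 4])
        spec = Multistage(1)
        fit = fit_mle(spec, ds)
        # force predictions to the observed proportions via a fake 2-param fit
        from bmdbatch.fitting import DoseResponseResults

        class Oracle(Multistage):
            def predict(self, params, doses):
                return np.array([0.1, 0.2, 0.4])[: len(np.atleast_1d(doses))]

        ofit = DoseResponseResults(Oracle(1), ds, np.array([0.1, 0.2]), 0.0, True)
        p, chi2, df = gof_dichotomous(ofit, ds)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)
        del fit

    def test_known_quantile(self):
        assert stats.chi2.sf(3.84, 1) == pytest.approx(0.05, abs=5e-4)

    def test_matches_direct_summation(self, dich_dataset):
        fit = fit_mle(Logistic(), dich_dataset)
        p, chi2, df = gof_dichotomous(fit, dich_dataset)
        phat = np.clip(fit.predicted, 1e-8, 1 - 1e-8)
        n, y = dich_dataset.n, dich_dataset.incidence
        oracle = float(np.sum((y - n * phat) ** 2 / (n * phat * (1 - phat))))
        assert chi2 == pytest.approx(oracle, abs=1e-10)
        assert df == dich_dataset.n_groups - 2

    def test_df_below_one_not_computable(self):
        ds = DoseResponseDataset("g", "dichotomous", [0, 10, 100], [20, 20, 20],
                                 incidence=[1, 5, 12])
        fit = fit_mle(Multistage(2), ds)  # 3 params, 3 groups
        assert fit.gof_pvalue is None


class TestContinuousTests:
    def test_exact_linear_data_test4_stat_zero(self):
        doses = np.array([0.0, 10.0, 30.0, 100.0])
        mean = 50.0 + 1.5 * doses
        ds = DoseResponseDataset("lin", "continuous", doses, [15] * 4,
                                 mean=mean, sd=[8.0] * 4)
        fit = fit_mle(Polynomial(1, variance_mode="constant"), ds)
        # the line passes exactly through every group mean
        assert fit.tests["test4_p"] == pytest.approx(1.0, abs=1e-6)

    def test_homogeneous_data_test2_large_p(self):
        ds = DoseResponseDataset("h", "continuous", [0, 10, 100], [30, 30, 30],
                                 mean=[10.0, 12.0, 15.0], sd=[2.0, 2.0, 2.0])
        t = continuous_lr_tests(ds, None)
        assert t["test2_p"] == pytest.approx(1.0, abs=1e-9)

    def test_heterogeneous_data_test2_small_p(self):
        ds = DoseResponseDataset("h", "continuous", [0, 10, 100], [30, 30, 30],
                                 mean=[10.0, 12.0, 15.0], sd=[1.0, 4.0, 12.0])
        t = continuous_lr_tests(ds, None)
        assert t["test2_p"] < 0.001

    def test_strong_response_test1_small_p(self, cont_dataset):
        t = continuous_lr_tests(cont_dataset, None)
        assert t["test1_p"] < 1e-10
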