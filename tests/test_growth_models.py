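"""Curve-form evaluation and fitting against independent oracles."""

import numpy as np
import pytest

from standgrowth.errors import DomainError, SingularDesignError, UndefinedR2Error
from standgrowth.growth_models import (
    FAMILIES,
    LINEARIZABLE,
    ModelForm,
    default_init,
    fit_closed_form,
    fit_nls,
    goodness_of_fit,
    linear_basis,
    predict,
)


def draw_sane_params(form, rng):
    """Random parameters in ranges that keep responses well scaled."""
    f = form.family
    base = {
        "linear": [rng.uniform(0, 10), rng.uniform(0.1, 1)],
        "logarithmic": [rng.uniform(-5, 5), rng.uniform(0.5, 5)],
        "reciprocal": [rng.uniform(5, 25), rng.uniform(-150, -10)],
        "quadratic": [rng.uniform(-3, 3), rng.uniform(0.2, 1.5),
                      rng.uniform(-0.03, -0.005)],
        "cubic": [rng.uniform(-3, 3), rng.uniform(0.5, 2),
                  rng.uniform(-0.08, -0.02), rng.uniform(0.0005, 0.002)],
        "s_curve": [rng.uniform(2, 3.6), rng.uniform(-18, -4)],
        "growth": [rng.uniform(1, 2.5), rng.uniform(0.005, 0.05)],
        "logistic": [rng.uniform(8, 25), rng.uniform(0.15, 0.6),
                     rng.uniform(10, 25)],
    }[f]
    return np.array(base + [rng.uniform(-0.3, 0.3)
                            for _ in range(form.n_covariates)])


def design_for(form, rng, n=120):
    x1 = rng.uniform(5, 40, n)
    if form.n_covariates == 0:
        return x1
    return np.column_stack(
        [x1] + [rng.uniform(-1, 1, n) for _ in range(form.n_covariates)]
    )


class TestPredict:
    def test_logistic_halfway_at_inflection(self):
        # at x = b3 the exponent vanishes, so y = b1/2
        form = ModelForm("logistic")
        y = predict(form, [19.835, 0.205, 16.246], [16.246])
        assert y[0] == pytest.approx(19.835 / 2, abs=1e-12)

    def test_linear_identity_line(self):
        assert predict(ModelForm("linear"), [0, 1], [5.0])[0] == 5.0

    def test_growth_at_zero_is_exp_intercept(self):
        y = predict(ModelForm("growth"), [2.053, 0.008], [0.0])
        assert y[0] == pytest.approx(np.exp(2.053), rel=1e-12)

    def test_reciprocal_domain_error_at_zero(self):
        with pytest.raises(DomainError):
            predict(ModelForm("reciprocal"), [1, 1], [0.0])

    def test_overflow_returns_nonfinite_not_crash(self):
        y = predict(ModelForm("growth"), [0.0, 1.0], [5000.0])
        assert np.isinf(y[0])

    def test_param_count_checked(self):
        with pytest.raises(ValueError):
            predict(ModelForm("linear"), [1.0], [1.0])


class TestReductionIdentity:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_zero_covariate_coefficients_reduce_exactly(self, family, rng):
        basic = ModelForm(family)
        multi = ModelForm(family, n_covariates=3)
        params = draw_sane_params(basic, rng)
        full = np.concatenate([params, np.zeros(3)])
        n = 1000
        x1 = rng.uniform(1, 40, n)
        X = np.column_stack([x1, rng.normal(0, 5, (n, 3))])
        a = predict(basic, params, x1)
        b = predict(multi, full, X)
        assert np.array_equal(a, b)


class TestShapeProperties:
    def test_logistic_properties(self, rng):
        b1, b2, b3 = 19.0, 0.3, 15.0
        form = ModelForm("logistic")
        assert predict(form, [b1, b2, b3], [b3])[0] == pytest.approx(b1 / 2)
        x = np.linspace(1, 60, 200)
        y = predict(form, [b1, b2, b3], x)
        assert np.all(np.diff(y) > 0)  # increasing iff b2 > 0
        y_dec = predict(form, [b1, -b2, b3], x)
        assert np.all(np.diff(y_dec) < 0)
        far = predict(form, [b1, b2, b3], [b3 + 1e6 / b2])[0]
        assert far == pytest.approx(b1, rel=1e-9)

    def test_s_curve_increasing_with_asymptote(self):
        b0, b1 = 3.4, -12.9
        x = np.linspace(0.5, 500, 400)
        y = predict(ModelForm("s_curve"), [b0, b1], x)
        assert np.all(np.diff(y) > 0)
        assert y[-1] < np.exp(b0)
        assert predict(ModelForm("s_curve"), [b0, b1], [1e9])[0] == pytest.approx(
            np.exp(b0), rel=1e-6)

    def test_nesting_monotonicity(self, rng):
        x = rng.uniform(1, 30, 50)
        y = 2 + 0.4 * x + rng.normal(0, 2, 50)
        r2 = {
            fam: fit_closed_form(ModelForm(fam), x, y).r2
            for fam in ("linear", "quadratic", "cubic")
        }
        assert r2["cubic"] >= r2["quadratic"] >= r2["linear"]


class TestClosedForm:
    def test_exact_linear_recovery(self):
        x = np.arange(1.0, 11.0)
        res = fit_closed_form(ModelForm("linear"), x, 2 + 3 * x)
        assert res.params == pytest.approx([2.0, 3.0], abs=1e-10)
        assert res.r2 == pytest.approx(1.0)

    def test_exact_s_curve_recovery_on_log_scale(self):
        x = np.array([5.0, 10.0, 20.0, 40.0])
        y = np.exp(3.174 - 8.341 / x)
        res = fit_closed_form(ModelForm("s_curve"), x, y)
        assert res.params == pytest.approx([3.174, -8.341], abs=1e-9)
        assert res.r2 == pytest.approx(1.0)
        assert res.fit_scale == "log"

    @pytest.mark.parametrize("family", LINEARIZABLE)
    def test_matches_normal_equation_oracle(self, family, rng):
        form = ModelForm(family)
        x = rng.uniform(2, 40, 25)
        y = rng.uniform(1, 30, 25)
        res = fit_closed_form(form, x, y)
        design, logresp = linear_basis(form, x)
        resp = np.log(y) if logresp else y
        oracle = np.linalg.solve(design.T @ design, design.T @ resp)
        assert res.params == pytest.approx(oracle, abs=1e-8)

    def test_log_form_rejects_nonpositive_response(self):
        with pytest.raises(DomainError):
            fit_closed_form(ModelForm("growth"), np.arange(1.0, 6.0),
                            np.array([1.0, 2.0, -1.0, 3.0, 4.0]))

    def test_rank_deficient_design_raises(self):
        x = np.full(10, 7.0)
        with pytest.raises(SingularDesignError):
            fit_closed_form(ModelForm("linear"), x, np.arange(10.0))


class TestGoodnessOfFit:
    def test_perfect_and_null_fits(self, rng):
        y = rng.normal(10, 2, 30)
        r2, f, df1, df2, p = goodness_of_fit(y, y, 1)
        assert r2 == 1.0 and p == 0.0
        r2, f, *_ = goodness_of_fit(y, np.full_like(y, y.mean()), 1)
        assert r2 == pytest.approx(0.0, abs=1e-12)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_anova(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        x = rng.uniform(0, 10, 20)
        y = 1 + 2 * x + rng.normal(0, 1, 20)
        model = sm.OLS(y, sm.add_constant(x)).fit()
        fitted = model.fittedvalues
        r2, f, df1, df2, p = goodness_of_fit(y, fitted, 1)
        assert r2 == pytest.approx(model.rsquared, abs=1e-10)
        assert f == pytest.approx(model.fvalue, abs=1e-8)
        assert p == pytest.approx(model.f_pvalue, abs=1e-10)

    def test_constant_response_undefined(self):
        with pytest.raises(UndefinedR2Error):
            goodness_of_fit(np.full(10, 3.0), np.arange(10.0), 1)


class TestDefaultInit:
    def test_logistic_asymptote_rule(self, rng):
        x = np.linspace(1, 30, 50)
        y = predict(ModelForm("logistic"), [10 / 1.0, 0.3, 15], x)
        y = y / y.max() * 10.0  # force max y = 10
        init = default_init(ModelForm("logistic"), x, y)
        assert init[0] == pytest.approx(10.5)

    def test_logistic_slope_sign_matches_monotonicity(self):
        x = np.linspace(1, 30, 60)
        y = predict(ModelForm("logistic"), [20, 0.4, 15], x)
        init = default_init(ModelForm("logistic"), x, y)
        assert init[1] > 0

    def test_multivariate_start_appends_zeros(self):
        x = np.array([5.0, 10.0, 20.0, 40.0])
        y = np.exp(3.174 - 8.341 / x)
        form = ModelForm("s_curve", n_covariates=3)
        X = np.column_stack([x, np.zeros((4, 3))])
        init = default_init(form, X, y)
        assert init == pytest.approx([3.174, -8.341, 0, 0, 0], abs=1e-9)


class TestNLS:
    @pytest.mark.parametrize("family", FAMILIES)
    @pytest.mark.parametrize("n_cov", [0, 3])
    def test_zero_noise_recovery(self, family, n_cov, rng):
        form = ModelForm(family, n_cov)
        for _ in range(3):
            X = design_for(form, rng)
            p = draw_sane_params(form, rng)
            y = predict(form, p, X)
            res = fit_nls(form, X, y)
            rel = np.abs((res.params - p) / np.where(p != 0, p, 1.0))
            assert res.converged
            assert np.max(rel) < 1e-6

    def test_noisy_logistic_recovery(self, rng):
        truth = np.array([19.835, 0.205, 16.246])
        form = ModelForm("logistic")
        x = rng.uniform(1, 40, 500)
        y = predict(form, truth, x) + rng.normal(0, 0.5, 500)
        res = fit_nls(form, x, y)
        assert res.converged
        assert np.max(np.abs((res.params - truth) / truth)) < 0.05

    def test_constant_response_flagged_not_crash(self):
        x = np.linspace(1, 30, 40)
        y = np.full(40, 5.0)
        res = fit_nls(ModelForm("logistic"), x, y)
        assert not res.converged or abs(res.params[0] - 5.0) / 5.0 < 0.5

    def test_insufficient_df_raises(self):
        with pytest.raises(ValueError):
            fit_nls(ModelForm("cubic"), np.arange(1.0, 5.0), np.arange(4.0))

    def test_serialization_round_trip(self, rng):
        x = rng.uniform(1, 30, 30)
        y = 1 + 2 * x + rng.normal(0, 0.1, 30)
        d = fit_closed_form(ModelForm("linear"), x, y).to_dict()
        assert d["form_id"] == "basic_linear"
        assert len(d["params"]) == 2 and d["converged"]
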