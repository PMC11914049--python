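"""Design standardization, HDI machinery, diagnostics, and model fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import approx_fprime

from reefkit import hbm
from reefkit._nuts import nuts_sample
from reefkit.hbm import (
    ModelSpec,
    _GammaModel,
    _NormalModel,
    bayes_r2,
    classify_trend,
    fit_hbm,
    gelman_rubin,
    hdi,
    screen_collinearity,
    standardize_design,
)


class TestStandardize:
    def test_three_point_column(self):
        out, _ = standardize_design(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert out["x"].to_numpy() == pytest.approx([-0.5, 0.0, 0.5])

    def test_mean_zero_sd_half(self, rng):
        frame = pd.DataFrame({"x": rng.normal(3, 2, 200)})
        out, _ = standardize_design(frame)
        assert out["x"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["x"].std(ddof=1) == pytest.approx(0.5)

    def test_balanced_binary_indicator(self):
        x = pd.DataFrame({"b": [0.0] * 50 + [1.0] * 50})
        out, _ = standardize_design(x)
        sd = np.std(x["b"], ddof=1)
        assert out["b"].max() == pytest.approx(0.5 / (2 * sd))
        assert out["b"].max() == pytest.approx(0.4975, abs=1e-3)

    def test_constant_column_named_in_error(self):
        with pytest.raises(ValueError, match="'c'"):
            standardize_design(pd.DataFrame({"c": [1.0, 1.0, 1.0]}))

    def test_scaling_record_invertible(self, rng):
        frame = pd.DataFrame({"x": rng.normal(5, 3, 50)})
        out, rec = standardize_design(frame)
        back = out["x"] * 2 * rec.sds["x"] + rec.means["x"]
        assert back.to_numpy() == pytest.approx(frame["x"].to_numpy())


class TestHdi:
    def test_normal_draws_match_quantiles(self, rng):
        draws = rng.standard_normal(10_000)
        low, high = hdi(draws, 0.95)
        assert low == pytest.approx(-1.96, abs=0.07)
        assert high == pytest.approx(1.96, abs=0.07)

    def test_uniform_width(self, rng):
        draws = rng.uniform(0, 1, 20_000)
        low, high = hdi(draws, 0.80)
        assert high - low == pytest.approx(0.80, abs=0.02)

    def test_point_mass_zero_width(self):
        low, high = hdi(np.full(500, 3.3), 0.95)
        assert low == high == 3.3

    def test_matches_arviz(self, rng):
        az = pytest.importorskip("arviz")
        draws = rng.gamma(2.0, 1.0, 5000)
        low, high = hdi(draws, 0.9)
        ref = az.hdi(draws, hdi_prob=0.9)
        # conventions differ by one draw in the interval count; agree closely
        assert low == pytest.approx(ref[0], abs=0.02)
        assert high == pytest.approx(ref[1], abs=0.02)

    def test_nesting(self, rng):
        draws = rng.standard_normal(5000)
        l80, h80 = hdi(draws, 0.80)
        l95, h95 = hdi(draws, 0.95)
        assert l95 <= l80 and h80 <= h95


@pytest.mark.parametrize(
    "interval, expected",
    [
        ((-0.5, -0.1), "credible_negative"),
        ((0.1, 0.5), "credible_positive"),
        ((-0.1, 0.2), "not_credible"),
        ((0.0, 0.3), "not_credible"),   # endpoint at zero counts as overlap
        ((-0.3, 0.0), "not_credible"),
    ],
)
def test_classify_trend(interval, expected):
    assert classify_trend(interval) == expected


class TestGelmanRubin:
    def test_identical_chains_near_one(self, rng):
        chain = rng.standard_normal(1000)
        assert gelman_rubin(np.vstack([chain, chain])) == pytest.approx(1.0, abs=1e-3)

    def test_offset_chains_flagged(self, rng):
        a = rng.standard_normal(500)
        b = a + 10.0
        # hand evaluation of the classical PSRF formula
        w = (a.var(ddof=1) + b.var(ddof=1)) / 2
        b_over_n = np.var([a.mean(), b.mean()], ddof=1)
        expected = np.sqrt(((len(a) - 1) / len(a) * w + b_over_n) / w)
        assert gelman_rubin(np.vstack([a, b])) == pytest.approx(expected)
        assert gelman_rubin(np.vstack([a, b])) > 1.1

    def test_zero_within_variance_is_inf(self):
        chains = np.vstack([np.zeros(100), np.ones(100)])
        assert gelman_rubin(chains) == np.inf


class TestCollinearity:
    def test_orthogonal_columns(self):
        frame = pd.DataFrame({"a": [1, -1, 1, -1], "b": [1, 1, -1, -1.0]})
        report = screen_collinearity(frame)
        assert report["vif"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_duplicate_column_infinite(self, rng):
        x = rng.normal(size=50)
        report = screen_collinearity(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(report["vif"]).all()

    def test_known_correlation_closed_form(self, rng):
        # two predictors with r = 0.6 -> VIF = 1/(1-0.36) = 1.5625
        n = 100_000
        a = rng.standard_normal(n)
        b = 0.6 * a + np.sqrt(1 - 0.36) * rng.standard_normal(n)
        report = screen_collinearity(pd.DataFrame({"a": a, "b": b}))
        assert report["vif"]["a"] == pytest.approx(1.5625, rel=0.02)
        assert abs(report["correlation"].loc["a", "b"]) == pytest.approx(0.6, abs=0.02)


class TestBayesR2:
    def test_known_variances(self):
        # predicted values with variance 4, residual variance 1 -> R^2 = 0.8
        mu = np.tile(np.array([0.0, 2.0, 4.0, 6.0]), (200, 1))  # var (ddof=1) ~ 6.67
        var_pred = np.var(mu[0], ddof=1)
        sigma2 = np.full(200, 1.0)
        out = bayes_r2(mu, sigma2)
        assert out["median"] == pytest.approx(var_pred / (var_pred + 1.0))

    def test_bounded_in_unit_interval(self, rng):
        mu = rng.normal(size=(300, 40))
        sigma2 = rng.gamma(2, 1, 300)
        out = bayes_r2(mu, sigma2)
        assert 0.0 <= out["median"] <= 1.0
        assert 0.0 <= out["hdi95_low"] <= out["hdi95_high"] <= 1.0


class TestLogPosteriors:
    def test_normal_model_gradient(self, rng):
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ np.array([1.0, -0.5, 0.3]) + rng.normal(0, 0.5, n)
        model = _NormalModel(
            X, y, 10.0, 1e-2, rng.integers(0, 4, n), rng.integers(0, 3, n)
        )
        z = rng.normal(0, 0.3, model.dim)
        _, grad = model.logp_and_grad(z)
        numeric = approx_fprime(z, lambda zz: model.logp_and_grad(zz)[0], 1e-6)
        assert grad == pytest.approx(numeric, rel=1e-3, abs=1e-3)

    def test_gamma_model_gradient(self, rng):
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = rng.gamma(4.0, 1.0, n) + 0.1
        model = _GammaModel(X, y, 20.0, 1e-2)
        z = rng.normal(0, 0.2, model.dim)
        _, grad = model.logp_and_grad(z)
        numeric = approx_fprime(z, lambda zz: model.logp_and_grad(zz)[0], 1e-6)
        assert grad == pytest.approx(numeric, rel=1e-3, abs=1e-3)

    def test_gamma_rejects_zero_counts(self, rng):
        X = np.ones((5, 1))
        with pytest.raises(ValueError, match="strictly positive"):
            _GammaModel(X, np.array([1.0, 0.0, 2.0, 3.0, 4.0]), 20.0, 1e-2)


class TestSampler:
    def test_standard_normal_target(self, rng):
        res = nuts_sample(
            lambda z: (-0.5 * float(z @ z), -z), np.zeros(4), 500, 3000, rng
        )
        assert res.draws.mean(axis=0) == pytest.approx(np.zeros(4), abs=0.08)
        assert res.draws.std(axis=0) == pytest.approx(np.ones(4), abs=0.08)

    def test_correlated_gaussian_target(self, rng):
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        prec = np.linalg.inv(cov)

        def logp(z):
            return -0.5 * float(z @ prec @ z), -prec @ z

        res = nuts_sample(logp, np.zeros(2), 500, 4000, rng)
        emp = np.cov(res.draws.T)
        assert emp == pytest.approx(cov, abs=0.12)


def _block_data(seed, n_years=12, beta=(0.5, 1.0, -0.5, 0.8, 0.0, 0.0), eps=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    for year in range(1, n_years + 1):
        for proc in (0.0, 1.0):
            for depth in (2.0, 5.0, 8.0):
                rows.append({"surface_processing": proc, "depth": depth, "years": float(year)})
    d = pd.DataFrame(rows)
    std, _ = standardize_design(d)
    mu = (
        beta[0] + beta[1] * std["surface_processing"] + beta[2] * std["depth"]
        + beta[3] * std["years"] + beta[4] * std["surface_processing"] * std["depth"]
        + beta[5] * std["surface_processing"] * std["years"]
    )
    d["alr"] = mu + rng.normal(0, eps, len(d))
    return d


FAST = dict(tune=300, draws=600, repetitions=2)


class TestFitHbm:
    def test_eq2_recovers_truth_within_hdi95(self):
        data = _block_data(seed=5)
        fit = fit_hbm(ModelSpec("eq2_block_cover", **FAST), data, "alr", seed=3)
        truth = {"intercept": 0.5, "surface_processing": 1.0, "depth": -0.5, "years": 0.8}
        for name, value in truth.items():
            row = fit.table.loc[name]
            assert row["hdi95_low"] <= value <= row["hdi95_high"], name

    def test_draw_bookkeeping_matches_protocol(self):
        data = _block_data(seed=6)
        spec = ModelSpec("eq2_block_cover", **FAST)
        fit = fit_hbm(spec, data, "alr", seed=1)
        for d in fit.draws.values():
            assert d.shape == (spec.repetitions, spec.draws)

    def test_fit_is_reproducible(self):
        data = _block_data(seed=7)
        f1 = fit_hbm(ModelSpec("eq2_block_cover", tune=150, draws=200, repetitions=2), data, "alr", seed=9)
        f2 = fit_hbm(ModelSpec("eq2_block_cover", tune=150, draws=200, repetitions=2), data, "alr", seed=9)
        assert np.array_equal(f1.draws["years"], f2.draws["years"])

    def test_gamma_fitted_mean_positive(self):
        rng = np.random.default_rng(11)
        data = _block_data(seed=8)
        mu = np.exp(1.0 + 0.5 * np.linspace(-1, 1, len(data)))
        data["colony"] = rng.gamma(mu**2, 1.0 / mu)
        fit = fit_hbm(ModelSpec("eq3_colony", **FAST), data, "colony", seed=2)
        assert fit.table.loc["intercept", "median"] > 0  # log-scale intercept of positive mean
        assert (fit.pooled("eps3") > 0).all()

    def test_default_spec_matches_protocol_constants(self):
        spec = ModelSpec("eq1_cover")
        assert (spec.tune, spec.draws, spec.repetitions) == (1000, 2000, 5)
        assert spec.prior_bound == 10.0
        assert ModelSpec("eq3_colony").prior_bound == 20.0
        assert spec.halfcauchy_scale == pytest.approx(1e-2)
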