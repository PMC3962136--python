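"""Multinomial-logit and ordered-logit fitting against closed forms and
independent reference implementations."""

import numpy as np
import pytest
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from mccit.data import LabeledDataset
from mccit.glm import (
    MultinomialLogit,
    OrderedLogit,
    fit_multinomial_logit,
    fit_ordered_logit,
    intercept_only_loglik,
)
from mccit.synthetic import gen_categorical_dataset, gen_ordinal_dataset

LL_532 = 5 * np.log(0.5) + 3 * np.log(0.3) + 2 * np.log(0.2)


class TestInterceptOnly:
    """Intercept-only MLEs are saturated: fitted probabilities equal the
    empirical class frequencies and the log-likelihood has a closed form."""

    def test_multinomial(self):
        y = np.repeat([0, 1, 2], [5, 3, 2])
        res = MultinomialLogit(y).fit()
        assert res.log_lik == pytest.approx(LL_532, abs=1e-10)
        probs = res.predict_proba(np.empty((1, 0)))[0]
        assert probs == pytest.approx([0.5, 0.3, 0.2], abs=1e-10)
        assert res.n_params == 2

    def test_ordered(self):
        y = np.repeat([0, 1, 2], [5, 3, 2])
        res = OrderedLogit(y).fit()
        assert res.log_lik == pytest.approx(LL_532, abs=1e-10)
        # cumulative probabilities at the thresholds = empirical (0.5, 0.8)
        from scipy.special import expit

        assert expit(res.thresholds) == pytest.approx([0.5, 0.8], abs=1e-9)
        assert res.n_params == 2

    def test_closed_form_helper(self):
        assert intercept_only_loglik([5, 3, 2]) == pytest.approx(LL_532)


class TestBinaryReduction:
    """With K=2 both families collapse to ordinary logistic regression."""

    @pytest.fixture
    def binary(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((150, 2))
        eta = 0.8 * X[:, 0] - 0.5 * X[:, 1] + 0.2
        y = (rng.random(150) < 1 / (1 + np.exp(-eta))).astype(int)
        return X, y

    def test_multinomial_matches_logit(self, binary):
        X, y = binary
        res = MultinomialLogit(y, X).fit()
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert res.log_lik == pytest.approx(ref.llf, abs=1e-6)
        # our baseline is class 1 (last), statsmodels models P(y=1):
        # coefficients for class 0 vs baseline are the negated logit params
        assert res.coefficients[0] == pytest.approx(-ref.params, abs=1e-4)

    def test_ordered_matches_logit(self, binary):
        X, y = binary
        res = OrderedLogit(y, X).fit()
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert res.log_lik == pytest.approx(ref.llf, abs=1e-6)
        # P(y=1) = expit(x b - mu_1): intercept corresponds to -mu_1
        assert -res.thresholds[0] == pytest.approx(ref.params[0], abs=1e-4)
        assert res.slope == pytest.approx(ref.params[1:], abs=1e-4)


class TestParameterRecovery:
    """Refitting data simulated from known coefficients recovers them, with
    error shrinking as n grows."""

    def test_multinomial_recovery(self):
        data, truth = gen_categorical_dataset(5000, 2, 3, 2, effect_size=1.0, seed=5)
        res = fit_multinomial_logit(data, truth.relevant_features)
        est = res.coefficients[:, 1:]
        assert np.abs(est - truth.generating_params["coefficients"]).max() < 0.1

    def test_ordered_recovery(self):
        data, truth = gen_ordinal_dataset(5000, 2, 4, 2, effect_size=1.0, seed=6)
        res = fit_ordered_logit(data, truth.relevant_features)
        assert np.abs(res.slope - truth.generating_params["slope"]).max() < 0.1
        assert np.abs(
            res.thresholds - truth.generating_params["thresholds"]
        ).max() < 0.1

    @pytest.mark.parametrize("family", ["nominal", "ordinal"])
    def test_error_shrinks_with_n(self, family):
        errs = []
        for n in (500, 5000):
            if family == "nominal":
                data, truth = gen_categorical_dataset(n, 2, 3, 2, 1.0, seed=9)
                res = fit_multinomial_logit(data, truth.relevant_features)
                err = np.abs(
                    res.coefficients[:, 1:] - truth.generating_params["coefficients"]
                ).max()
            else:
                data, truth = gen_ordinal_dataset(n, 2, 4, 2, 1.0, seed=9)
                res = fit_ordered_logit(data, truth.relevant_features)
                err = np.abs(res.slope - truth.generating_params["slope"]).max()
            errs.append(err)
        assert errs[1] < errs[0]


class TestLikelihoodProperties:
    def test_nested_model_monotonicity(self, nominal_dataset, ordinal_dataset):
        """Adding a regressor can never decrease the achieved maximum."""
        for data, fit in (
            (nominal_dataset[0], fit_multinomial_logit),
            (ordinal_dataset[0], fit_ordered_logit),
        ):
            ll_nested = fit(data, [0, 1]).log_lik
            ll_full = fit(data, [0, 1, 2]).log_lik
            assert ll_full >= ll_nested - 1e-8

    def test_affine_rescaling_invariance(self, nominal_dataset, ordinal_dataset):
        for (data, _), fit in (
            (nominal_dataset, fit_multinomial_logit),
            (ordinal_dataset, fit_ordered_logit),
        ):
            ll = fit(data, [0, 1]).log_lik
            scaled = LabeledDataset(
                data.features.copy(), data.outcome, data.outcome_kind
            )
            scaled.features[:, 0] = scaled.features[:, 0] * 1000.0 + 5.0
            ll_scaled = fit(scaled, [0, 1]).log_lik
            assert abs(ll - ll_scaled) < 1e-6

    def test_matches_statsmodels_mnlogit(self, nominal_dataset):
        data, _ = nominal_dataset
        res = fit_multinomial_logit(data, [0, 1, 2])
        ref = sm.MNLogit(
            data.outcome, sm.add_constant(data.features[:, :3])
        ).fit(disp=0)
        assert res.log_lik == pytest.approx(ref.llf, abs=1e-6)

    def test_matches_statsmodels_ordered(self, ordinal_dataset):
        data, _ = ordinal_dataset
        res = fit_ordered_logit(data, [0, 1])
        ref = OrderedModel(
            data.outcome, data.features[:, :2], distr="logit"
        ).fit(method="bfgs", disp=0)
        assert res.log_lik == pytest.approx(ref.llf, abs=1e-6)


class TestPredictProba:
    def test_symmetric_zero_coefficients(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        res = MultinomialLogit(y, np.zeros((6, 0))).fit()
        res.coefficients[:] = 0.0
        probs = res.predict_proba(np.empty((4, 0)))
        assert probs == pytest.approx(np.full((4, 3), 1 / 3), abs=1e-12)

    def test_rows_sum_to_one(self, nominal_dataset, ordinal_dataset):
        for (data, _), fit in (
            (nominal_dataset, fit_multinomial_logit),
            (ordinal_dataset, fit_ordered_logit),
        ):
            res = fit(data, [0, 1, 2])
            probs = res.predict_proba(data.features[:, :3])
            assert probs.min() >= 0
            assert np.abs(probs.sum(axis=1) - 1).max() < 1e-12

    def test_ordered_zero_slope_gives_threshold_marginals(self):
        y = np.repeat([0, 1, 2], [5, 3, 2])
        res = OrderedLogit(y, np.zeros((10, 0))).fit()
        from scipy.special import expit

        res.slope = np.zeros(2)
        probs = res.predict_proba(np.random.default_rng(0).normal(size=(5, 2)))
        cum = expit(res.thresholds)
        expected = np.diff(np.concatenate([[0.0], cum, [1.0]]))
        for row in probs:
            assert row == pytest.approx(expected, abs=1e-12)

    def test_scalar_formula_oracle(self):
        """predict_proba agrees with per-sample evaluation of the displayed
        logit formulas by an independent scalar implementation."""
        rng = np.random.default_rng(8)
        y = rng.integers(0, 3, 60)
        y[:3] = [0, 1, 2]
        X = rng.standard_normal((60, 2))
        res = MultinomialLogit(y, X).fit()
        row = X[7]
        # scalar: Pr(k)/Pr(K) = exp(b_k . w), probabilities sum to one
        ratios = [
            np.exp(res.coefficients[k, 0] + res.coefficients[k, 1:] @ row)
            for k in range(2)
        ] + [1.0]
        expected = np.array(ratios) / np.sum(ratios)
        assert res.predict_proba(row[None])[0] == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_raises(self, nominal_dataset):
        data, _ = nominal_dataset
        res = fit_multinomial_logit(data, [0, 1])
        with pytest.raises(ValueError):
            res.predict_proba(data.features[:, :3])


class TestRankHandling:
    def test_constant_and_duplicate_columns_dropped(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 3, 100)
        y[:3] = [0, 1, 2]
        x = rng.standard_normal(100)
        X = np.column_stack([x, np.full(100, 7.0), 2.0 * x])
        res = MultinomialLogit(y, X).fit()
        assert res.dropped_columns == [1, 2]
        assert res.n_params == 2 * 2  # intercept + 1 kept regressor, K-1 = 2
        ref = MultinomialLogit(y, X[:, :1]).fit()
        assert res.log_lik == pytest.approx(ref.log_lik, abs=1e-8)

    def test_separation_stays_finite(self):
        """Perfectly separated data must not diverge: coefficients stay
        within the optimization box and the log-likelihood is finite."""
        x = np.concatenate([-np.ones(10), np.ones(10)])
        y = (x > 0).astype(int)
        res = MultinomialLogit(y, x[:, None]).fit()
        assert np.isfinite(res.log_lik)
        assert np.abs(res.coefficients).max() <= 30.0 + 1e-9

    def test_ordinal_outcome_required(self, nominal_dataset):
        data, _ = nominal_dataset
        with pytest.raises(ValueError):
            fit_ordered_logit(data, [0])
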