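"""Conditional independence tests: worked values, independent oracles, and
calibration properties."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import optimize, stats

from mccit.cit import (
    CITConfig,
    FisherZ,
    G2,
    MCCIT,
    discretize_three_bins,
    fisher_z_cit,
    g2_cit,
    make_cit,
    mc_cit,
)
from mccit.data import LabeledDataset
from mccit.synthetic import (
    gen_categorical_dataset,
    gen_null_triplet,
    gen_ordinal_dataset,
)


def brute_force_mnl_loglik(X, y, k):
    """Independent multinomial log-likelihood maximized with a generic
    optimizer; shares no code with the package's Newton fitter."""
    n, q = X.shape
    W = np.column_stack([np.ones(n), X])

    def negll(theta):
        eta = np.column_stack([W @ theta.reshape(k - 1, q + 1).T, np.zeros(n)])
        m = eta.max(axis=1, keepdims=True)
        logz = m[:, 0] + np.log(np.exp(eta - m).sum(axis=1))
        return -(eta[np.arange(n), y] - logz).sum()

    res = optimize.minimize(
        negll, np.zeros((k - 1) * (q + 1)), method="BFGS",
        options={"gtol": 1e-9, "maxiter": 2000},
    )
    return -res.fun


class TestMcCit:
    def test_zero_variance_x(self, nominal_dataset):
        data, _ = nominal_dataset
        feats = data.features.copy()
        feats[:, 3] = 1.5
        d = LabeledDataset(feats, data.outcome, "nominal")
        res = mc_cit(d, 3, (0,))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_duplicate_of_conditioning_variable(self, nominal_dataset):
        data, _ = nominal_dataset
        feats = data.features.copy()
        feats[:, 3] = feats[:, 0] * 2.0  # collinear with cond member
        d = LabeledDataset(feats, data.outcome, "nominal")
        res = mc_cit(d, 3, (0, 1))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_x_in_cond_raises(self, nominal_dataset):
        with pytest.raises(ValueError):
            mc_cit(nominal_dataset[0], 0, (0, 1))

    @pytest.mark.parametrize("cond", [(), (1,), (1, 2)])
    def test_brute_force_lrt_oracle(self, cond):
        """The D statistic matches an independent generic-optimizer
        computation of both nested log-likelihoods."""
        data, _ = gen_categorical_dataset(200, 4, 3, 2, effect_size=0.8, seed=21)
        res = mc_cit(data, 0, cond)
        ll_full = brute_force_mnl_loglik(
            data.features[:, list(cond) + [0]], data.outcome, 3
        )
        ll_alt = brute_force_mnl_loglik(data.features[:, list(cond)], data.outcome, 3)
        assert res.statistic == pytest.approx(2 * (ll_full - ll_alt), abs=1e-4)

    @pytest.mark.parametrize("kind", ["nominal", "ordinal"])
    def test_binary_reduction_to_logistic_lrt(self, kind):
        """For K=2 the test is the ordinary binary logistic LRT, whichever
        outcome declaration is used."""
        for seed in range(10):
            data, _ = (
                gen_categorical_dataset(120, 3, 2, 1, 0.8, seed=seed)
                if kind == "nominal"
                else gen_ordinal_dataset(120, 3, 2, 1, 0.8, seed=seed)
            )
            res = mc_cit(data, 0, (1,))
            full = sm.Logit(
                data.outcome, sm.add_constant(data.features[:, [1, 0]])
            ).fit(disp=0)
            alt = sm.Logit(
                data.outcome, sm.add_constant(data.features[:, [1]])
            ).fit(disp=0)
            expected = stats.chi2.sf(2 * (full.llf - alt.llf), 1)
            assert res.df == 1
            assert res.p_value == pytest.approx(expected, abs=1e-6)

    def test_baseline_invariance(self, nominal_dataset):
        """Permuting nominal class codes leaves the LRT statistic unchanged:
        the test must not depend on which class is the reference."""
        data, _ = nominal_dataset
        base = mc_cit(data, 0, (1,)).statistic
        for perm in ([1, 2, 0], [2, 0, 1], [0, 2, 1]):
            relabeled = np.asarray(perm)[data.outcome]
            d = LabeledDataset(data.features, relabeled, "nominal")
            assert mc_cit(d, 0, (1,)).statistic == pytest.approx(base, abs=1e-6)

    def test_df_conventions(self, nominal_dataset, ordinal_dataset):
        nom, _ = nominal_dataset
        orn, _ = ordinal_dataset
        assert mc_cit(nom, 0, ()).df == 2  # K-1 extra parameters for K=3
        assert mc_cit(orn, 0, ()).df == 1  # one extra slope for ordered logit
        one = CITConfig(df_convention="paper_one_df")
        assert mc_cit(nom, 0, (), one).df == 1

    def test_null_calibration_quick(self):
        """Conditional null: rejection rate near alpha (wide tolerance; the
        tight calibration check lives in the acceptance suite)."""
        rej = 0
        for s in range(200):
            d, _ = gen_null_triplet(150, 3, 2, seed=90_000 + s)
            rej += mc_cit(d, 0, (1, 2)).p_value <= 0.05
        assert 0.02 <= rej / 200 <= 0.09

    def test_power_increases_with_n_and_effect(self):
        """Rejection of a genuinely relevant feature becomes more frequent
        with more samples and with stronger effects."""
        def power(n, eff, reps=60):
            hits = 0
            for s in range(reps):
                d, tr = gen_categorical_dataset(n, 2, 3, 1, eff, seed=1000 + s)
                hits += mc_cit(d, tr.relevant_features[0], ()).p_value <= 0.05
            return hits / reps

        p50, p150, p500 = power(50, 0.4), power(150, 0.4), power(500, 0.4)
        assert p50 <= p150 + 0.1 and p150 <= p500 + 0.1 and p500 > p50
        assert power(150, 1.0) > power(150, 0.2)


class TestFisherZ:
    def test_exact_half_correlation(self):
        """Constructed binary outcome with sample correlation exactly 0.5 at
        n=103: z = atanh(0.5) ~ 0.54931, statistic = 10*z, p ~ 3.95e-8."""
        n = 103
        y = np.zeros(n, dtype=int)
        y[:40] = 1
        yc = y - y.mean()
        rng = np.random.default_rng(0)
        e = rng.standard_normal(n)
        e -= e.mean()
        e -= yc * (yc @ e) / (yc @ yc)  # orthogonal to centered outcome
        e *= np.linalg.norm(yc) / np.linalg.norm(e)
        x = yc + np.sqrt(3.0) * e  # corr(x, y) = 1/2 exactly
        d = LabeledDataset(np.column_stack([x, rng.standard_normal(n)]), y, "nominal")
        res = fisher_z_cit(d, 0, ())
        assert res.statistic == pytest.approx(np.sqrt(100) * np.arctanh(0.5), abs=1e-9)
        assert res.statistic == pytest.approx(5.4931, abs=1e-4)
        assert res.p_value == pytest.approx(3.95e-8, rel=2e-3)

    def test_orthogonal_gives_p_one(self):
        n = 50
        y = np.array([0, 1] * 25)
        x = np.tile([1.0, -1.0, -1.0, 1.0], 13)[:n]  # orthogonal to y pattern
        x -= x.mean()
        x -= (y - y.mean()) * ((y - y.mean()) @ x) / ((y - y.mean()) @ (y - y.mean()))
        d = LabeledDataset(np.column_stack([x, np.ones(n) + np.arange(n)]), y, "nominal")
        res = fisher_z_cit(d, 0, ())
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("n_cond", [1, 2])
    def test_partial_correlation_matrix_oracle(self, n_cond):
        """The residual-based partial correlation equals the one implied by
        inverting the joint correlation matrix (independent route)."""
        data, _ = gen_categorical_dataset(150, 5, 3, 2, 0.8, seed=33)
        cond = tuple(range(1, 1 + n_cond))
        res = fisher_z_cit(data, 0, cond)
        cols = np.column_stack(
            [data.features[:, 0], data.outcome.astype(float)]
            + [data.features[:, j] for j in cond]
        )
        prec = np.linalg.inv(np.corrcoef(cols, rowvar=False))
        r = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        expected_stat = np.sqrt(len(data.outcome) - n_cond - 3) * abs(np.arctanh(r))
        assert res.statistic == pytest.approx(expected_stat, abs=1e-10)

    def test_insufficient_sample_not_assessable(self):
        d = LabeledDataset(np.random.default_rng(1).normal(size=(5, 4)),
                           np.array([0, 1, 0, 1, 0]), "nominal")
        res = fisher_z_cit(d, 0, (1, 2))
        assert not res.assessable
        assert res.p_value == 1.0


class TestDiscretization:
    def test_constant_vector_all_medium(self):
        assert discretize_three_bins([3.0] * 7).tolist() == [1] * 7

    def test_worked_example(self):
        codes = discretize_three_bins([0, 0, 0, 0, 10.0])
        assert codes.tolist() == [1, 1, 1, 1, 2]

    def test_normal_sample_bin_proportions(self):
        rng = np.random.default_rng(4)
        codes = discretize_three_bins(rng.standard_normal(200_000))
        props = np.bincount(codes, minlength=3) / len(codes)
        assert props == pytest.approx([0.1587, 0.6827, 0.1587], abs=0.01)


class TestG2:
    def _dataset(self, table):
        """Build x/y code vectors realizing a 2x2 contingency table."""
        xs, ys = [], []
        for i, row in enumerate(table):
            for j, cnt in enumerate(row):
                xs += [i] * cnt
                ys += [j] * cnt
        return np.array(xs)[:, None], np.array(ys)

    def test_diagonal_table_worked_example(self):
        x, y = self._dataset([[10, 0], [0, 10]])
        res = g2_cit(x, y, 0, (), CITConfig(g2_hpa=1))
        assert res.statistic == pytest.approx(40 * np.log(2), abs=1e-10)
        assert res.df == 1
        assert res.p_value == pytest.approx(1.4e-7, rel=5e-2)

    def test_proportional_table_gives_zero(self):
        x, y = self._dataset([[5, 5], [5, 5]])
        res = g2_cit(x, y, 0, (), CITConfig(g2_hpa=1))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_power_heuristic_forgoes_small_samples(self):
        """n=20 with a 3-level x, 3 classes and a 3-level conditioning
        variable needs n >= 5 * 12; the test must decline."""
        rng = np.random.default_rng(0)
        x = np.tile([0, 1, 2], 7)[:20]
        z = rng.integers(0, 3, 20)
        y = rng.integers(0, 3, 20)
        y[:3] = [0, 1, 2]
        res = g2_cit(np.column_stack([x, z]), y, 0, (1,), CITConfig(g2_hpa=5))
        assert not res.assessable
        assert res.p_value == 1.0
        assert res.df == 12

    def test_single_level_x_not_assessable(self):
        res = g2_cit(np.zeros((30, 1), dtype=int), np.tile([0, 1, 2], 10), 0, ())
        assert not res.assessable

    def test_empty_strata_reduce_df(self):
        """Unobserved conditioning-level combinations contribute no degrees
        of freedom: two perfectly correlated binary conditioners span 4
        nominal strata but only 2 observed ones."""
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, 40)
        z1 = np.array([0, 1] * 20)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        res = g2_cit(np.column_stack([x, z1, z1]), y, 0, (1, 2), CITConfig(g2_hpa=1))
        assert res.df == 2  # (2-1)(2-1) per observed stratum, 2 of 4 observed

    def test_callable_wrapper_discretizes(self, nominal_dataset):
        data, _ = nominal_dataset
        test = make_cit("g2", CITConfig(g2_hpa=1))
        res = test(data, 0, ())
        assert res.test_name == "g2"
        assert 0 <= res.p_value <= 1


class TestUniformContract:
    @pytest.mark.parametrize("kind", ["mc_cit", "fisher_z", "g2"])
    def test_make_cit_contract(self, kind, nominal_dataset):
        data, _ = nominal_dataset
        test = make_cit(kind)
        res = test(data, 0, (1,))
        assert res.test_name in (kind, "g2")
        assert 0 <= res.p_value <= 1
        assert res.df >= 1

    def test_mccit_cache_consistency(self, nominal_dataset):
        data, _ = nominal_dataset
        test = MCCIT()
        r1 = test(data, 0, (1, 2))
        r2 = test(data, 0, (1, 2))
        assert r1.p_value == r2.p_value
        assert mc_cit(data, 0, (1, 2)).p_value == pytest.approx(r1.p_value, abs=1e-9)

    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError):
            make_cit("chi2")
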