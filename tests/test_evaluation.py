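"""Phenotype preparation, CV model builder, and comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from multipgs import (
    MixWeights,
    aggregate_bhhr,
    correlation_with_se,
    cross_validate_top1,
    hotelling_williams,
    prepare_phenotype,
    relative_improvement,
    weight_rmse,
)


class TestPreparePhenotype:
    def test_blom_three_value_example(self):
        y = pd.Series([1.2, 5.5, 3.3])
        ranks = np.array([1, 3, 2])
        expected = stats.norm.ppf((ranks - 3 / 8) / (3 + 1 / 4))
        # worked example: (-0.8694, 0.8694, 0) before scaling
        np.testing.assert_allclose(expected, [-0.8694, 0.8694, 0.0], atol=1e-4)
        out = prepare_phenotype(pd.concat([y] * 4, ignore_index=True))  # n>=10
        assert out.mean() == pytest.approx(0.0, abs=1e-6)
        assert out.std(ddof=0) == pytest.approx(1.0, abs=1e-6)

    def test_rank_invariance_under_monotone_transform(self, rng):
        y = pd.Series(rng.gamma(2, 1, 100))
        a = prepare_phenotype(y)
        b = prepare_phenotype(np.exp(y))
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_transform_close_to_normal(self, rng):
        y = pd.Series(rng.exponential(1, 10_000))
        out = prepare_phenotype(y)
        d = stats.kstest((out - out.mean()) / out.std(), "norm").statistic
        assert d < 0.02

    def test_covariate_residualization(self, rng):
        n = 500
        cov = pd.DataFrame({"age": rng.normal(50, 10, n)})
        y = pd.Series(0.1 * cov["age"] + rng.standard_normal(n))
        out = prepare_phenotype(y, cov)
        assert abs(np.corrcoef(out, cov["age"])[0, 1]) < 0.2
        assert out.mean() == pytest.approx(0.0, abs=1e-6)

    def test_constant_trait_raises(self):
        with pytest.raises(ValueError):
            prepare_phenotype(pd.Series(np.ones(20)))


class TestCorrelationWithSe:
    def test_identical_vectors(self, rng):
        x = rng.standard_normal(50)
        r, se = correlation_with_se(x, x)
        assert r == pytest.approx(1.0)

    def test_orthogonal_vectors(self, rng):
        x = rng.standard_normal(1000)
        y = rng.standard_normal(1000)
        y = y - x * (x @ y) / (x @ x)
        x = x - x.mean()
        y = y - y.mean()
        y = y - x * (x @ y) / (x @ x)
        r, _ = correlation_with_se(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_sampling_distribution(self, rng):
        n = 10_000
        x = rng.standard_normal(n)
        y = 0.3 * x + np.sqrt(1 - 0.09) * rng.standard_normal(n)
        r, se = correlation_with_se(x, y)
        assert r == pytest.approx(0.3, abs=0.03)
        assert se == pytest.approx(np.sqrt((1 - r**2) / (n - 2)))

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            correlation_with_se(np.ones(10), np.arange(10.0))


class TestCrossValidateTop1:
    def test_single_candidate_is_plain_cv_correlation(self, rng):
        n = 400
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        res = cross_validate_top1(pd.DataFrame({"s": x}), y, k=10, seed=0)
        r_plain = np.corrcoef(x, y)[0, 1]
        assert res.r == pytest.approx(r_plain, abs=0.05)

    def test_phenotype_as_candidate_selected_everywhere(self, rng):
        n = 300
        y = rng.standard_normal(n)
        cands = pd.DataFrame({"truth": y, "noise": rng.standard_normal(n)})
        res = cross_validate_top1(cands, y, k=10, seed=1)
        assert res.r == pytest.approx(1.0, abs=1e-8)
        assert all(s["scores"] == "truth" for s in res.selected)

    def test_known_signal_with_distractors_no_optimism(self, rng):
        n = 5000
        y = rng.standard_normal(n)
        signal = 0.5 * y + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        cands = {"grp": pd.DataFrame({"signal": signal, **{f"n{i}": rng.standard_normal(n) for i in range(5)}})}
        res = cross_validate_top1(cands, y, k=10, seed=2)
        assert res.r == pytest.approx(0.5, abs=0.05)
        assert res.r < 0.5 + 2 * res.se

    def test_pure_noise_candidates_no_selection_optimism(self, rng):
        n = 2000
        y = rng.standard_normal(n)
        cands = pd.DataFrame(rng.standard_normal((n, 100)), columns=[f"c{i}" for i in range(100)])
        res = cross_validate_top1(cands, y, k=10, seed=3)
        assert abs(res.r) < 3 * res.se

    def test_k_exceeding_n_raises(self, rng):
        with pytest.raises(ValueError):
            cross_validate_top1(pd.DataFrame({"s": np.arange(5.0)}), np.arange(5.0), k=10)


class TestHotellingWilliams:
    @staticmethod
    def textbook_oracle(r12, r13, r23, n):
        # independently coded from the textbook formula
        detR = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
        rbar = 0.5 * (r13 + r23)
        t = (r13 - r23) * np.sqrt(
            ((n - 1) * (1 + r12)) / (2 * detR * (n - 1) / (n - 3) + rbar**2 * (1 - r12) ** 3)
        )
        return t, 2 * stats.t.sf(abs(t), n - 3)

    def test_equal_correlations_give_null(self):
        t, p = hotelling_williams(0.5, 0.4, 0.4, 100)
        assert t == 0.0 and p == 1.0

    def test_matches_formula_oracle(self):
        t, p = hotelling_williams(0.5, 0.4, 0.3, 100)
        t0, p0 = self.textbook_oracle(0.5, 0.4, 0.3, 100)
        assert t == pytest.approx(t0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_antisymmetry(self):
        t1, _ = hotelling_williams(0.6, 0.5, 0.2, 200)
        t2, _ = hotelling_williams(0.6, 0.2, 0.5, 200)
        assert t1 == pytest.approx(-t2, abs=1e-12)

    def test_non_psd_inputs_raise(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            hotelling_williams(-0.9, 0.9, 0.9, 50)

    def test_null_rejection_rate_calibrated(self):
        # two equally predictive models; type-I error at alpha=0.05
        rng = np.random.default_rng(42)
        n, sims = 500, 2000
        rej = 0
        rho = 0.4
        for _ in range(sims):
            y = rng.standard_normal(n)
            e = rng.standard_normal((n, 2))
            m1 = rho * y + np.sqrt(1 - rho**2) * e[:, 0]
            m2 = rho * y + np.sqrt(1 - rho**2) * e[:, 1]
            r12 = np.corrcoef(m1, m2)[0, 1]
            r13 = np.corrcoef(m1, y)[0, 1]
            r23 = np.corrcoef(m2, y)[0, 1]
            _, p = hotelling_williams(r12, r13, r23, n)
            rej += p < 0.05
        assert 0.03 <= rej / sims <= 0.07

    def test_agrees_with_permutation_null(self):
        # fixed toy dataset: compare the analytic p against the null obtained
        # by randomly exchanging the two model predictions per sample and
        # recomputing the Williams t
        rng = np.random.default_rng(3)
        n = 1000
        y = rng.standard_normal(n)
        m1 = 0.5 * y + rng.standard_normal(n)
        m2 = 0.5 * y + rng.standard_normal(n)

        def williams_t(a, b):
            r12 = np.corrcoef(a, b)[0, 1]
            r13 = np.corrcoef(a, y)[0, 1]
            r23 = np.corrcoef(b, y)[0, 1]
            return hotelling_williams(r12, r13, r23, n)

        t_obs, p_analytic = williams_t(m1, m2)
        exceed = 0
        n_perm = 10_000
        for _ in range(n_perm):
            swap = rng.random(n) < 0.5
            a = np.where(swap, m2, m1)
            b = np.where(swap, m1, m2)
            t_perm, _ = williams_t(a, b)
            exceed += abs(t_perm) >= abs(t_obs)
        assert abs(exceed / n_perm - p_analytic) < 0.01


class TestAggregateBhhr:
    def test_single_trait_identity(self):
        r, se = aggregate_bhhr([0.3], [0.01], [[1.0]])
        assert r == 0.3 and se == pytest.approx(0.1)

    def test_independent_traits_closed_form(self):
        m, se0 = 4, 0.05
        r, se = aggregate_bhhr([0.2] * m, [se0**2] * m, np.eye(m))
        assert se == pytest.approx(se0 / np.sqrt(m), abs=1e-12)

    def test_correlated_traits_double_sum_oracle(self):
        rvals = np.array([0.2, 0.3, 0.4])
        se0 = 0.05
        rho = np.full((3, 3), 0.5)
        np.fill_diagonal(rho, 1.0)
        r, se = aggregate_bhhr(rvals, [se0**2] * 3, rho)
        # independent direct summation
        acc = sum(rho[i, j] * se0 * se0 for i in range(3) for j in range(3)) / 9
        assert r == pytest.approx(0.3)
        assert se == pytest.approx(np.sqrt(acc), abs=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            aggregate_bhhr([0.1, 0.2], [0.01, 0.01], np.eye(3))


class TestWeightRmse:
    def mk(self, pops, alpha):
        return MixWeights(pops, np.asarray(alpha, dtype=float), "IndivTune")

    def test_identical_weights_zero(self):
        assert weight_rmse(self.mk(["A", "B"], [0.3, 0.1]), self.mk(["A", "B"], [0.3, 0.1])) == 0.0

    def test_hand_arithmetic(self):
        got = weight_rmse(self.mk(["A", "B"], [0.5, 0.1]), self.mk(["A", "B"], [0.3, 0.3]))
        assert got == pytest.approx(0.2)

    def test_invariant_to_joint_permutation(self):
        a = weight_rmse(self.mk(["A", "B"], [0.5, 0.1]), self.mk(["B", "A"], [0.3, 0.3]))
        b = weight_rmse(self.mk(["B", "A"], [0.1, 0.5]), self.mk(["A", "B"], [0.3, 0.3]))
        assert a == pytest.approx(b)

    def test_population_mismatch_raises(self):
        with pytest.raises(ValueError):
            weight_rmse(self.mk(["A", "B"], [0.1, 0.2]), self.mk(["A", "C"], [0.1, 0.2]))


class TestRelativeImprovement:
    def test_equal_models_zero_percent(self):
        assert relative_improvement(0.2, 0.2)["percent"] == 0.0

    def test_ten_percent(self):
        assert relative_improvement(0.22, 0.20)["percent"] == pytest.approx(10.0)

    def test_antisymmetry_identity(self):
        r_a, r_b = 0.25, 0.2
        fwd = relative_improvement(r_a, r_b)["percent"]
        rev = relative_improvement(r_b, r_a)["percent"]
        assert fwd == pytest.approx(-rev * r_a / r_b, abs=1e-10)

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            relative_improvement(0.1, 0.0)

    def test_se_propagation_positive(self):
        out = relative_improvement(0.22, 0.2, se_a=0.01, se_b=0.01, r_ab=0.9)
        assert out["se"] > 0
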