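"""Negative-binomial GLM engine: size factors, dispersion, fits, Wald tests."""

import numpy as np
import pandas as pd
import pytest

from hrsip.io import CountMatrix
from hrsip.nb import (
    dispersion_mom,
    estimate_dispersion,
    estimate_size_factors,
    fit_nb_glm,
    nb_loglik,
    wald_one_sided,
    wald_two_sided,
)


def cm_from(arr, prefix="s"):
    arr = np.atleast_2d(arr)
    return CountMatrix(
        pd.DataFrame(
            arr,
            index=[f"o{i}" for i in range(arr.shape[0])],
            columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
        )
    )


class TestSizeFactors:
    def test_identical_samples(self):
        m = cm_from(np.tile([[5], [9], [14]], (1, 2)))
        assert estimate_size_factors(m).tolist() == pytest.approx([1.0, 1.0])

    def test_doubled_sample(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 40, size=12)
        m = cm_from(np.column_stack([col, 2 * col]))
        sf = estimate_size_factors(m)
        # median of ratios against per-OTU geometric means, geomean rescaled to 1
        assert sf.tolist() == pytest.approx([1 / np.sqrt(2), np.sqrt(2)], abs=1e-6)

    def test_global_rescaling_invariance(self, small_counts):
        base = small_counts.data + 1  # avoid the poscounts fallback switching
        sf1 = estimate_size_factors(CountMatrix(base))
        sf2 = estimate_size_factors(CountMatrix(base * 3))
        assert sf1.tolist() == pytest.approx(sf2.tolist(), abs=1e-9)

    def test_all_zero_sample_rejected(self):
        m = cm_from(np.array([[1, 0], [2, 0]]))
        with pytest.raises(ValueError, match="all-zero"):
            estimate_size_factors(m)

    def test_poscounts_fallback_on_sparse_data(self):
        rng = np.random.default_rng(5)
        data = rng.integers(0, 6, size=(30, 6))
        data[:, 0] = np.maximum(data[:, 0], 1)  # keep every sample non-empty
        sf = estimate_size_factors(cm_from(data))
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)
        assert (sf > 0).all()


class TestDispersion:
    def test_method_of_moments_example(self):
        # mean 25, sample variance 500/3: (166.667 - 25) / 625
        assert dispersion_mom(np.array([10, 20, 30, 40.0])) == pytest.approx(0.22667, abs=1e-4)

    def test_poisson_counts_give_near_zero_alpha(self):
        rng = np.random.default_rng(123)
        y = rng.poisson(50, size=200)
        m = cm_from(y)
        alpha = estimate_dispersion(m, np.ones((200, 1)), pd.Series(1.0, index=m.sample_ids))
        assert alpha.iloc[0] < 0.02

    def test_nb_alpha_recovery(self):
        rng = np.random.default_rng(42)
        k = 2.0  # alpha = 0.5
        y = rng.negative_binomial(k, k / (k + 50), size=500)
        m = cm_from(y)
        alpha = estimate_dispersion(m, np.ones((500, 1)), pd.Series(1.0, index=m.sample_ids))
        assert 0.4 <= alpha.iloc[0] <= 0.6

    def test_median_recovery_across_seeds(self):
        # parameter recovery: median alpha-hat within 25% of truth at n=200, mu=20
        truth = 0.5
        k = 1 / truth
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.negative_binomial(k, k / (k + 20), size=200)
            m = cm_from(y)
            a = estimate_dispersion(m, np.ones((200, 1)), pd.Series(1.0, index=m.sample_ids))
            estimates.append(a.iloc[0])
        assert abs(np.median(estimates) - truth) / truth < 0.25

    def test_collinear_design_rejected(self, small_counts):
        X = np.column_stack([np.ones(4), np.ones(4)])
        sf = pd.Series(1.0, index=small_counts.sample_ids)
        with pytest.raises(ValueError, match="collinear"):
            estimate_dispersion(small_counts, X, sf)


two_group = np.column_stack([np.ones(4), [0, 0, 1, 1.0]])


class TestNbGlm:
    def test_two_group_closed_form(self):
        # alpha = 0: NB MLE equals log2 ratio of group means (ridge-bounded)
        fit = fit_nb_glm(np.array([10, 10, 40, 40.0]), two_group, np.ones(4), 0.0)
        assert fit.converged
        assert fit.coef[1] == pytest.approx(2.0, abs=0.01)

    def test_identical_groups_symmetric(self):
        fit = fit_nb_glm(np.array([20, 20, 20, 20.0]), two_group, np.ones(4), 0.0)
        assert abs(fit.coef[1]) < 0.01

    def test_all_zero_group_finite(self):
        fit = fit_nb_glm(np.array([30, 30, 0, 0.0]), two_group, np.ones(4), 0.1)
        assert fit.converged
        assert np.isfinite(fit.coef[1]) and fit.coef[1] < -3

    def test_poisson_saturated_fit_matches_group_means(self):
        # Poisson GLM identity with unit size factors: fitted cell means
        # equal arithmetic means of counts (checked with a near-flat ridge)
        rng = np.random.default_rng(7)
        y = rng.poisson([5, 5, 5, 30, 30, 30]).astype(float)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1.0]])
        fit = fit_nb_glm(y, X, np.ones(6), 0.0, ridge_var=1e8)
        assert 2 ** fit.coef[0] == pytest.approx(y[:3].mean(), rel=1e-4)
        assert 2 ** (fit.coef[0] + fit.coef[1]) == pytest.approx(y[3:].mean(), rel=1e-4)

    def test_poisson_fit_with_offsets_matches_ratio_of_totals(self):
        # with unequal size factors the Poisson MLE solves
        # sum(y) = 2^eta * sum(sf) within each design cell
        rng = np.random.default_rng(8)
        y = rng.poisson([5, 5, 5, 30, 30, 30]).astype(float)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1.0]])
        sf = np.array([1, 1.2, 0.8, 1, 1.1, 0.9])
        fit = fit_nb_glm(y, X, sf, 0.0, ridge_var=1e8)
        assert 2 ** fit.coef[0] == pytest.approx(y[:3].sum() / sf[:3].sum(), rel=1e-4)
        assert 2 ** (fit.coef[0] + fit.coef[1]) == pytest.approx(
            y[3:].sum() / sf[3:].sum(), rel=1e-4
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_local_optimum_against_grid(self, seed):
        # brute-force likelihood grid search around the optimum
        rng = np.random.default_rng(seed)
        y = rng.negative_binomial(2, 0.2, size=8).astype(float)
        X = np.column_stack([np.ones(8), rng.integers(0, 2, 8).astype(float)])
        if np.ptp(X[:, 1]) == 0:
            X[0, 1] = 1 - X[0, 1]
        alpha = 0.3
        fit = fit_nb_glm(y, X, np.ones(8), alpha, ridge_var=1e8)

        def penll(b):
            mu = np.exp(np.log(2) * (X @ b))
            return nb_loglik(y, mu, alpha)

        best = fit.coef
        for db0 in np.linspace(-0.5, 0.5, 11):
            for db1 in np.linspace(-0.5, 0.5, 11):
                assert penll(best) >= penll(best + [db0, db1]) - 1e-6

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            fit_nb_glm(np.array([1, 2, 3, 4.0]), two_group, np.ones(4), -0.1)


class TestWald:
    def test_one_sided_tail(self):
        assert wald_one_sided(3.0, 0.5, 2.0) == pytest.approx(0.0227501, abs=1e-6)

    def test_at_threshold_half(self):
        assert wald_one_sided(2.0, 1.0, 2.0) == pytest.approx(0.5)

    def test_below_threshold_above_half(self):
        assert wald_one_sided(1.0, 1.0, 2.0) > 0.5

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_one_sided(1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            wald_two_sided(1.0, -1.0)

    def test_two_sided_symmetry(self):
        assert wald_two_sided(1.5, 0.5) == pytest.approx(wald_two_sided(-1.5, 0.5))
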