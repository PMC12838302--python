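"""GMM estimation of (w, alpha, sigma_g2) from bin-variance tables."""

import numpy as np
import pandas as pd
import pytest

import alphamix as am
from alphamix.fit import analytic_sigma_g, fit_fixed_w, null_loss, _prepare

from conftest import make_noiseless_table


def brute_force_sigma(A, B, beta2, g):
    """Grid minimization of the quadratic sigma loss A*s^2 - B*s.

    Independent of the closed form: the one-bin solutions 2*b_k/g_k
    bracket the weighted minimizer; coarse zooms narrow the bracket and
    a final 1e5-point grid locates the minimum.
    """
    ob = 2 * np.asarray(beta2) / np.asarray(g)
    lo, hi = float(ob.min()), float(ob.max())
    if lo == hi:
        return lo
    for n_pts in (10_001, 10_001, 10_001, 100_001):
        grid = np.linspace(lo, hi, n_pts)
        c0 = grid[np.argmin(A * grid**2 - grid * B)]
        step = grid[1] - grid[0]
        lo, hi = c0 - 2 * step, c0 + 2 * step
    return float(c0)


def random_table(rng, k=30):
    return pd.DataFrame(
        {
            "trait": "t",
            "bin": np.arange(k),
            "n": rng.integers(50, 5000, k).astype(float),
            "mean_pA": rng.uniform(0.005, 0.5, k),
            "mean_pE": rng.uniform(0.05, 0.5, k),
            "beta2_hat": rng.normal(1.0, 0.5, k),
        }
    )


class TestPredict:
    def test_alpha_zero_is_flat(self):
        pred = am.predict_bin_variance(0.3, 0.0, 4.0, [0.1, 0.2, 0.5], [0.1, 0.2, 0.5])
        np.testing.assert_allclose(pred, 2.0)

    def test_closed_form_value(self):
        """p(1-p)=0.25 at p=0.5: 0.25^(-0.38) = 1.69349."""
        pred = am.predict_bin_variance(0.5, -0.38, 2.0, [0.5], [0.5])
        assert pred[0] == pytest.approx(0.25 ** (-0.38), rel=1e-12)
        assert pred[0] == pytest.approx(1.69349, abs=1e-4)

    def test_mixture_swap_symmetry(self):
        rng = np.random.default_rng(0)
        pA, pE = rng.uniform(0.01, 0.5, 20), rng.uniform(0.05, 0.5, 20)
        a = am.predict_bin_variance(0.7, -0.4, 1.5, pA, pE)
        b = am.predict_bin_variance(0.3, -0.4, 1.5, pE, pA)
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestAnalyticSigma:
    def test_single_bin_closed_form(self):
        tab = pd.DataFrame(
            {"trait": "t", "bin": [0], "n": [10], "mean_pA": [0.2],
             "mean_pE": [0.3], "beta2_hat": [0.8]}
        )
        g = (0.5 * 0.2 + 0.5 * 0.3) * (1 - (0.5 * 0.2 + 0.5 * 0.3))
        g = g ** (-0.4)
        assert am.analytic_sigma(0.5, -0.4, tab) == pytest.approx(2 * 0.8 / g)

    def test_alpha_zero_weighted_mean_rule(self):
        rng = np.random.default_rng(1)
        tab = random_table(rng)
        s = am.analytic_sigma(0.5, 0.0, tab)
        assert s == pytest.approx(
            2 * np.average(tab["beta2_hat"], weights=tab["n"]), rel=1e-12
        )

    def test_matches_brute_force_grid(self):
        """Closed form vs two-stage 1e5-point grid on random tables."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            tab = random_table(rng)
            w, alpha = rng.uniform(-0.5, 1.5), rng.uniform(-1.5, 1.5)
            closed = am.analytic_sigma(w, alpha, tab)
            data = _prepare(tab)
            pm = np.clip(
                w * data.mean_pA[0] + (1 - w) * data.mean_pE[0], 1e-6, 0.5
            )
            g = (pm * (1 - pm)) ** alpha
            A = np.sum(data.n[0] * g**2) / 4.0
            B = np.sum(data.n[0] * data.beta2[0] * g)
            brute = brute_force_sigma(A, B, data.beta2[0], g)
            assert closed == pytest.approx(brute, rel=1e-6, abs=1e-12)

    def test_all_zero_transform_raises(self):
        with pytest.raises(ValueError):
            analytic_sigma_g(np.array([1.0]), np.array([1.0]), np.array([0.0]))


class TestLoss:
    def test_zero_at_exact_prediction(self, noiseless_table):
        loss = am.gmm_loss(0.8, -0.5, [3.0], [noiseless_table])
        assert loss == pytest.approx(0.0, abs=1e-20)

    def test_linear_in_weights(self, noiseless_table):
        tab = noiseless_table.copy()
        tab["beta2_hat"] = tab["beta2_hat"] * 1.3  # make residuals non-zero
        l1 = am.gmm_loss(0.5, -0.3, [2.0], [tab])
        tab2 = tab.copy()
        tab2["n"] = 2 * tab2["n"]
        assert am.gmm_loss(0.5, -0.3, [2.0], [tab2]) == pytest.approx(2 * l1)

    def test_analytic_sigma_minimizes(self):
        rng = np.random.default_rng(3)
        tab = random_table(rng)
        w, alpha = 0.4, -0.6
        s_star = am.analytic_sigma(w, alpha, tab)
        best = am.gmm_loss(w, alpha, [s_star], [tab])
        for ds in (-0.5, -0.01, 0.01, 0.5):
            assert am.gmm_loss(w, alpha, [s_star + ds], [tab]) >= best

    def test_mismatched_sigma_count(self, noiseless_table):
        with pytest.raises(ValueError, match="per trait"):
            am.gmm_loss(0.5, -0.3, [1.0, 2.0], [noiseless_table])


class TestFit:
    def test_noiseless_recovery(self, common_bins):
        _, summary = common_bins
        tab = make_noiseless_table(summary, w=0.6, alpha=-0.7, sigma2=1.3)
        fr = am.fit_joint([tab], seed=1)
        assert fr.w == pytest.approx(0.6, abs=1e-3)
        assert fr.alpha == pytest.approx(-0.7, abs=1e-3)
        assert fr.sigma2[0] == pytest.approx(1.3, rel=1e-3)
        assert fr.loss < 1e-15

    def test_one_trait_equals_per_trait(self, noiseless_table):
        a = am.fit_joint([noiseless_table], seed=2)
        b = am.fit_per_trait(noiseless_table, seed=2)
        assert a.w == b.w and a.alpha == b.alpha

    def test_scale_equivariance(self, common_bins):
        """beta2 -> c*beta2 fixes (w, alpha) and scales sigma by c."""
        _, summary = common_bins
        rng = np.random.default_rng(4)
        tab = make_noiseless_table(summary, w=0.9, alpha=-0.4, sigma2=2.0)
        tab["beta2_hat"] += rng.normal(0, 0.05, len(tab))
        fr1 = am.fit_joint([tab], seed=3)
        tab2 = tab.copy()
        tab2["beta2_hat"] = 5.0 * tab2["beta2_hat"]
        fr2 = am.fit_joint([tab2], seed=3)
        assert fr2.w == pytest.approx(fr1.w, abs=1e-4)
        assert fr2.alpha == pytest.approx(fr1.alpha, abs=1e-4)
        assert fr2.sigma2[0] == pytest.approx(5.0 * fr1.sigma2[0], rel=1e-4)
        assert fr2.scaled_mse == pytest.approx(fr1.scaled_mse, rel=1e-6)

    def test_ancestry_swap_maps_w_to_one_minus_w(self, common_bins):
        _, summary = common_bins
        rng = np.random.default_rng(5)
        tab = make_noiseless_table(summary, w=0.8, alpha=-0.5, sigma2=1.0)
        tab["beta2_hat"] += rng.normal(0, 0.02, len(tab))
        fr1 = am.fit_joint([tab], seed=4)
        swapped = tab.rename(columns={"mean_pA": "mean_pE", "mean_pE": "mean_pA"})
        fr2 = am.fit_joint([swapped], seed=4)
        assert fr2.w == pytest.approx(1.0 - fr1.w, abs=1e-3)
        assert fr2.alpha == pytest.approx(fr1.alpha, abs=1e-3)

    def test_identical_tables_match_joint(self, common_bins):
        _, summary = common_bins
        rng = np.random.default_rng(6)
        tab = make_noiseless_table(summary, w=0.7, alpha=-0.3, sigma2=1.0)
        tab["beta2_hat"] += rng.normal(0, 0.02, len(tab))
        joint = am.fit_joint([tab, tab.copy(), tab.copy()], seed=5)
        single = am.fit_per_trait(tab, seed=5)
        assert joint.w == pytest.approx(single.w, abs=1e-4)
        assert joint.alpha == pytest.approx(single.alpha, abs=1e-4)

    def test_nesting_of_scaled_mse(self, common_bins):
        """Free fit beats w=0, w=1 and the alpha=0 null on every dataset."""
        _, summary = common_bins
        rng = np.random.default_rng(7)
        tab = make_noiseless_table(summary, w=0.5, alpha=-0.4, sigma2=1.0)
        tab["beta2_hat"] += rng.normal(0, 0.1, len(tab))
        free = am.fit_joint([tab], seed=6)
        for w0 in (0.0, 1.0):
            assert free.scaled_mse <= fit_fixed_w([tab], w0).scaled_mse + 1e-12
        assert free.scaled_mse <= 1.0 + 1e-12  # alpha=0 null is 1 by construction

    def test_fixed_w_zero_is_european_only_alpha_model(self, common_bins):
        """At w=0 the model depends on pE alone (the standard alpha model)."""
        _, summary = common_bins
        rng = np.random.default_rng(8)
        tab = make_noiseless_table(summary, w=0.0, alpha=-0.45, sigma2=1.0)
        tab["beta2_hat"] += rng.normal(0, 0.02, len(tab))
        fr = fit_fixed_w([tab], 0.0)
        # shuffling the African means must not change the fit at w=0
        tab2 = tab.copy()
        tab2["mean_pA"] = rng.permutation(tab2["mean_pA"].to_numpy())
        fr2 = fit_fixed_w([tab2], 0.0)
        assert fr.alpha == pytest.approx(fr2.alpha, abs=1e-10)


class TestProfileAlphaOverW:
    def test_null_scaled_mse_is_one_and_minimum_at_mle(self, common_bins):
        _, summary = common_bins
        rng = np.random.default_rng(9)
        tab = make_noiseless_table(summary, w=0.9, alpha=-0.5, sigma2=1.0)
        tab["beta2_hat"] += rng.normal(0, 0.05, len(tab))
        null = fit_fixed_w([tab], 0.5, alpha_bounds=(0.0, 0.0))
        assert null.scaled_mse == pytest.approx(1.0, rel=1e-12)
        free = am.fit_joint([tab], seed=10)
        prof = am.profile_alpha_over_w([tab], np.linspace(-0.5, 1.5, 21))
        assert free.scaled_mse <= prof["scaled_mse"].min() + 1e-9

    def test_alpha_amplifies_below_true_w(self, common_bins):
        """On noiseless w*=1 tables, fixing w below the truth produces
        larger-magnitude exponents (the misfit is absorbed by alpha)."""
        _, summary = common_bins
        tab = make_noiseless_table(summary, w=1.0, alpha=-0.5, sigma2=1.0)
        prof = am.profile_alpha_over_w([tab], [1.0, 0.6, 0.2])
        a = prof.set_index("w")["alpha_hat"]
        assert a[1.0] == pytest.approx(-0.5, abs=1e-6)
        assert abs(a[0.6]) > abs(a[1.0])
        assert abs(a[0.2]) > abs(a[1.0])


class TestTraitSelection:
    def test_all_correlated_keeps_top_only(self):
        rg2 = np.full((3, 3), 0.5)
        np.fill_diagonal(rg2, 1.0)
        sel = am.select_independent_traits([10, 10, 10], [5e4, 9e4, 7e4], rg2)
        assert sel == [1]

    def test_uncorrelated_keeps_all_passing(self):
        rg2 = np.eye(4)
        sel = am.select_independent_traits(
            [10, 2, 10, 10], [5e4, 9e4, 7e4, 1e4], rg2
        )
        assert sorted(sel) == [0, 2]  # trait 1 fails z, trait 3 fails N*h2

    def test_greedy_trace_matches_brute_force(self):
        """5-trait toy instance against an explicit greedy enumeration."""
        nh2 = np.array([9e4, 8e4, 7e4, 6e4, 5e4])
        z = np.full(5, 10.0)
        rg2 = np.eye(5)
        rg2[0, 1] = rg2[1, 0] = 0.5   # 1 conflicts with 0
        rg2[2, 3] = rg2[3, 2] = 0.2   # 3 conflicts with 2
        sel = am.select_independent_traits(z, nh2, rg2)
        # greedy order 0,1,2,3,4: 1 rejected (vs 0), 3 rejected (vs 2)
        assert sel == [0, 2, 4]

    def test_asymmetric_matrix_rejected(self):
        rg2 = np.eye(2)
        rg2[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            am.select_independent_traits([10, 10], [5e4, 6e4], rg2)
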