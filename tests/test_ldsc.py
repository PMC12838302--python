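"""Bin-wise variance estimation: chi2 regression, per-allele conversion, meta."""

import numpy as np
import pandas as pd
import pytest

import alphamix as am
from alphamix.ldsc import normalize_table


class TestStratifiedRegression:
    def test_null_gwas_recovers_zero_tau_and_unit_intercept(self):
        panel = am.simulate_common_panel(30_000, seed=61)
        panel["beta"] = 0.0
        ss = am.simulate_sumstats_direct(panel, 20_000, seed=62)
        # one annotation over half the SNPs keeps the free intercept identified
        annot = np.zeros((len(panel), 1))
        annot[: len(panel) // 2, 0] = 1.0
        tau, intercept = am.fit_stratified_ldsc(ss["chi2"].to_numpy(), annot, 20_000)
        assert intercept == pytest.approx(1.0, abs=0.05)
        assert abs(tau[0]) < 5e-6

    def test_single_annotation_recovers_h2_over_m(self):
        """E[chi2] = 1 + N h2/M: tau-hat recovers the per-SNP heritability."""
        M, N, h2 = 4_000, 30_000, 0.4
        panel = am.simulate_common_panel(M, seed=63)
        cfg = am.GenerativeConfig(n_snps=M, n_causal=M, h2=h2, alpha_true=0.0, seed=63)
        annot = np.ones((M, 1))
        taus = []
        for r in range(30):
            pt = am.simulate_causal_effects(panel, cfg, seed=100 + r)
            ss = am.simulate_sumstats_direct(pt, N, seed=200 + r)
            tau, _ = am.fit_stratified_ldsc(
                ss["chi2"].to_numpy(), annot, N, free_intercept=False
            )
            taus.append(tau[0])
        assert np.mean(taus) == pytest.approx(h2 / M, rel=0.1)

    def test_duplicate_annotation_raises(self):
        annot = np.zeros((100, 2))
        annot[:50] = 1.0
        with pytest.raises(ValueError, match="collinear"):
            am.fit_stratified_ldsc(np.ones(100), annot, 1000)

    def test_exact_expected_chi2_recovers_tau_exactly(self, common_panel, common_bins):
        """On noiseless expected chi2, the regression is a linear identity."""
        bin_idx, summary = common_bins
        cfg = am.GenerativeConfig(n_snps=20_000, n_causal=20_000, seed=64)
        pt = am.simulate_causal_effects(common_panel, cfg, seed=65)
        p = pt["freq_eur"].to_numpy()
        h2_snp = 2 * p * (1 - p) * pt["beta"].to_numpy() ** 2
        N = 10_000
        chi2_exact = 1 + N * h2_snp
        occupied = summary["bin"].to_numpy()
        annot = am.build_annotation_matrix(bin_idx, 120)[:, occupied]
        tau, _ = am.fit_stratified_ldsc(chi2_exact, annot, N, free_intercept=False)
        expected = np.array(
            [h2_snp[bin_idx == b].mean() for b in occupied]
        )
        np.testing.assert_allclose(tau, expected, rtol=1e-8)


class TestPerAllele:
    def test_arithmetic(self):
        annot = np.array([[1.0]])
        assert am.per_allele_variance([1.8e-6], annot, [0.1])[0] == pytest.approx(1e-5)
        assert am.per_allele_variance([1.0], annot, [0.5])[0] == pytest.approx(2.0)
        assert am.per_allele_variance([0.0], annot, [0.3])[0] == 0.0

    def test_invalid_pe(self):
        with pytest.raises(ValueError):
            am.per_allele_variance([1.0], np.array([[1.0]]), [0.0])


class TestBinMeans:
    def test_constant_and_simple_means(self):
        summary = pd.DataFrame(
            {"bin": [0, 1], "n": [2, 1], "mean_pA": [0.1, 0.2], "mean_pE": [0.1, 0.2]}
        )
        beta2 = np.array([1e-6, 3e-6, 5e-6])
        bin_idx = np.array([0, 0, 1])
        tab = am.bin_mean_variance(beta2, bin_idx, summary)
        assert tab["beta2_hat"].tolist() == pytest.approx([2e-6, 5e-6])

    def test_negative_means_retained(self):
        summary = pd.DataFrame(
            {"bin": [0], "n": [2], "mean_pA": [0.1], "mean_pE": [0.1]}
        )
        tab = am.bin_mean_variance(np.array([-3.0, 1.0]), np.array([0, 0]), summary)
        assert tab["beta2_hat"].iloc[0] == pytest.approx(-1.0)

    def test_scale_equivariance(self, common_panel, common_bins):
        """Scaling effects by c scales every bin mean by c^2."""
        bin_idx, summary = common_bins
        cfg = am.GenerativeConfig(n_snps=20_000, n_causal=2_000, seed=66)
        pt = am.simulate_causal_effects(common_panel, cfg, seed=67)
        t1 = am.oracle_bin_variance(pt, bin_idx, summary)
        pt2 = pt.copy()
        pt2["beta"] = 2.0 * pt2["beta"]
        t2 = am.oracle_bin_variance(pt2, bin_idx, summary)
        np.testing.assert_allclose(t2["beta2_hat"], 4.0 * t1["beta2_hat"], rtol=1e-12)

    def test_oracle_noiseless_ldsc_equivalence(self):
        """With pE constant within bins, exact-chi2 regression equals oracle means."""
        rng = np.random.default_rng(5)
        m_per = 50
        pes = [0.1, 0.2, 0.3, 0.45]
        panel = pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(m_per * 4)],
                "pos_index": np.arange(m_per * 4),
                "freq_eur": np.repeat(pes, m_per),
                "freq_afr": rng.uniform(0.05, 0.5, m_per * 4),
            }
        )
        panel["maf_eur"] = panel["freq_eur"]
        panel["maf_afr"] = np.minimum(panel["freq_afr"], 1 - panel["freq_afr"])
        panel["beta"] = rng.normal(0, 1e-3, len(panel))
        bin_idx = np.repeat(np.arange(4), m_per)
        summary = pd.DataFrame(
            {
                "bin": np.arange(4),
                "n": m_per,
                "mean_pA": 0.2,
                "mean_pE": pes,
            }
        )
        p = panel["freq_eur"].to_numpy()
        N = 50_000
        chi2_exact = 1 + N * 2 * p * (1 - p) * panel["beta"].to_numpy() ** 2
        annot = am.build_annotation_matrix(bin_idx, 4)
        tau, _ = am.fit_stratified_ldsc(chi2_exact, annot, N, free_intercept=False)
        beta2 = am.per_allele_variance(tau, annot, p)
        est = am.bin_mean_variance(beta2, bin_idx, summary)
        oracle = am.oracle_bin_variance(panel, bin_idx, summary)
        np.testing.assert_allclose(
            est["beta2_hat"], oracle["beta2_hat"], rtol=1e-8
        )


class TestOracle:
    def test_single_causal_bin_value(self):
        panel = pd.DataFrame(
            {
                "maf_afr": [0.1, 0.1],
                "maf_eur": [0.2, 0.2],
                "beta": [0.01, 0.0],
            }
        )
        summary = pd.DataFrame(
            {"bin": [0], "n": [2], "mean_pA": [0.1], "mean_pE": [0.2]}
        )
        tab = am.oracle_bin_variance(panel, np.array([0, 0]), summary, causal_only=True)
        assert tab["beta2_hat"].iloc[0] == pytest.approx(1e-4)
        assert tab["n"].iloc[0] == 1

    def test_all_snp_mean_dilutes_by_causal_fraction(self, common_panel, common_bins):
        bin_idx, summary = common_bins
        cfg = am.GenerativeConfig(
            n_snps=20_000, n_causal=10_000, alpha_true=0.0, seed=68
        )
        pt = am.simulate_causal_effects(common_panel, cfg, seed=69)
        allsnp = am.oracle_bin_variance(pt, bin_idx, summary, causal_only=False)
        causal = am.oracle_bin_variance(pt, bin_idx, summary, causal_only=True)
        merged = allsnp.merge(causal, on="bin", suffixes=("_all", "_c"))
        big = merged[merged["n_all"] > 300]
        ratio = (big["beta2_hat_all"] / big["beta2_hat_c"]).mean()
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_determinism(self, common_panel, common_bins):
        bin_idx, summary = common_bins
        cfg = am.GenerativeConfig(n_snps=20_000, n_causal=500, seed=70)
        pt = am.simulate_causal_effects(common_panel, cfg, seed=71)
        a = am.oracle_bin_variance(pt, bin_idx, summary)
        b = am.oracle_bin_variance(pt, bin_idx, summary)
        pd.testing.assert_frame_equal(a, b)


class TestNormalizeAndMeta:
    def _table(self, vals, n=100):
        k = len(vals)
        return pd.DataFrame(
            {
                "trait": "t",
                "bin": np.arange(k),
                "n": n,
                "mean_pA": np.linspace(0.1, 0.4, k),
                "mean_pE": np.linspace(0.1, 0.4, k),
                "beta2_hat": vals,
            }
        )

    def test_self_normalization_mean_is_one(self):
        tab = normalize_table(self._table([1.0, 2.0, 3.0, 6.0]))
        assert np.average(tab["beta2_hat"], weights=tab["n"]) == pytest.approx(1.0)

    def test_identical_traits_combine_to_common_value(self):
        tabs = {f"t{i}": self._table([1.0, 2.0, 3.0, 2.0]) for i in range(3)}
        out = am.normalize_and_meta(tabs)
        expected = normalize_table(self._table([1.0, 2.0, 3.0, 2.0]))["beta2_hat"]
        np.testing.assert_allclose(out["combined"], expected, rtol=1e-12)
        np.testing.assert_allclose(out["between_trait_var"], 0.0, atol=1e-15)

    def test_nonpositive_normalizer_excluded(self):
        tabs = {
            "good": self._table([1.0, 2.0, 3.0, 2.0]),
            "bad": self._table([-1.0, -2.0, -3.0, -2.0]),
            "good2": self._table([2.0, 4.0, 6.0, 4.0]),
        }
        with pytest.warns(UserWarning, match="normalizer"):
            out = am.normalize_and_meta(tabs)
        assert (out["n_traits"] == 2).all()


class TestMetaAnalyze:
    def test_equal_estimates(self):
        m = am.meta_analyze([2.0, 2.0, 2.0], [0.5, 0.5, 0.5])
        assert m.re_estimate == pytest.approx(2.0)
        assert m.fe_estimate == pytest.approx(2.0)
        assert m.q_stat == pytest.approx(0.0)
        assert m.tau2 == 0.0

    def test_symmetric_average(self):
        m = am.meta_analyze([1.0, 3.0], [1.0, 1.0])
        assert m.fe_estimate == pytest.approx(2.0)

    def test_dersimonian_laird_hand_computation(self):
        """Hand-worked 3-trait table: Q=3, c=2, tau2=0.5, RE=2.0645."""
        est, var = [1.0, 2.0, 4.0], [1.0, 0.5, 2.0]
        w = 1 / np.asarray(var)
        fe = np.sum(w * est) / w.sum()
        q = float(np.sum(w * (est - fe) ** 2))
        c = w.sum() - np.sum(w**2) / w.sum()
        tau2 = max(0.0, (q - 2) / c)
        wre = 1 / (np.asarray(var) + tau2)
        re = float(np.sum(wre * est) / wre.sum())
        m = am.meta_analyze(est, np.sqrt(var))
        assert m.q_stat == pytest.approx(q)
        assert m.tau2 == pytest.approx(tau2)
        assert m.re_estimate == pytest.approx(re)
        assert m.fe_estimate == pytest.approx(fe)

    def test_re_ci_contains_fe_ci_under_heterogeneity(self):
        m = am.meta_analyze([0.0, 5.0, 10.0], [0.5, 0.5, 0.5])
        assert m.tau2 > 0
        assert m.re_ci95[0] <= m.fe_ci95[0] and m.re_ci95[1] >= m.fe_ci95[1]

    def test_nonfinite_se_excluded(self):
        with pytest.warns(UserWarning, match="excluding"):
            m = am.meta_analyze([1.0, 2.0, 3.0], [1.0, np.nan, 1.0])
        assert m.n_traits == 2
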