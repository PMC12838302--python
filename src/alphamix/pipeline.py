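"""End-to-end simulation study: simulate, estimate bin variances, fit.

One study run mirrors the full analysis at desk scale: a common-SNP
panel is drawn once per condition (true mixture weight), a 12x10
bivariate MAF binning scheme is built from the panel, and each
replicate simulates 25 traits (fresh causal effects and GWAS noise on
the shared panel, as with real genotypes), estimates per-bin per-allele
effect variances, and jointly fits (w, alpha) across the traits.
"""

from __future__ import annotations

import dataclasses
import logging
import time

import numpy as np
import pandas as pd

from . import fit as fitmod
from .binning import assign_bins, build_binning_scheme
from .config import StudyConfig
from .ldsc import (
    build_annotation_matrix,
    bin_mean_variance,
    fit_stratified_ldsc,
    oracle_bin_variance,
    per_allele_variance,
)
from .simulate import simulate_causal_effects, simulate_common_panel, simulate_sumstats_direct

logger = logging.getLogger(__name__)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Distinct 31-bit integer seeds derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _chi2_tables(panel, gen, annot, occupied, bin_summary, bin_idx, seeds):
    """Simulate traits, regress chi2 on annotations, return per-trait tables."""
    M = len(panel)
    chi2 = np.empty((M, gen.n_traits))
    for t in range(gen.n_traits):
        pt = simulate_causal_effects(panel, gen, seed=int(seeds[2 * t]))
        ss = simulate_sumstats_direct(pt, gen.gwas_n, seed=int(seeds[2 * t + 1]))
        chi2[:, t] = ss["chi2"].to_numpy()
    # the occupied-bin indicators partition the panel, so a free intercept
    # would be exactly collinear; the unlinked direct regime has intercept 1
    tau, _ = fit_stratified_ldsc(chi2, annot, gen.gwas_n, free_intercept=False)
    beta2 = per_allele_variance(tau, annot, panel["maf_eur"].to_numpy())
    # bin means of per-SNP beta2, all traits at once
    counts = annot.sum(axis=0)
    means = (annot.T @ beta2) / counts[:, None]
    tables = []
    for t in range(gen.n_traits):
        tab = bin_summary[["bin", "n", "mean_pA", "mean_pE"]].copy()
        tab.insert(0, "trait", f"trait_{t}")
        tab["beta2_hat"] = means[:, t]
        tables.append(tab)
    return tables


def _oracle_tables(panel, gen, bin_summary, bin_idx, seeds, causal_only):
    tables, snp_data = [], []
    for t in range(gen.n_traits):
        pt = simulate_causal_effects(panel, gen, seed=int(seeds[2 * t]))
        tab = oracle_bin_variance(
            pt, bin_idx, bin_summary, causal_only=causal_only, trait=f"trait_{t}"
        )
        tables.append(tab)
        mask = (pt["beta"].to_numpy() != 0.0) if causal_only else np.ones(len(pt), bool)
        mask &= bin_idx >= 0
        snp_data.append(
            fitmod.SnpLevelData(
                pA=pt["maf_afr"].to_numpy()[mask],
                pE=pt["maf_eur"].to_numpy()[mask],
                bin_idx=bin_idx[mask],
            )
        )
    return tables, snp_data


def run_condition(config: StudyConfig, true_w: float) -> pd.DataFrame:
    """All replicates for one generative mixture weight."""
    gen = dataclasses.replace(config.generative, w_true=float(true_w))
    seeds = _child_seeds(config.seed + int(round(1000 * true_w)), 2 + config.n_replicates)
    panel = simulate_common_panel(
        gen.n_snps, gen.drift_afr, gen.drift_eur, seed=int(seeds[0])
    )
    scheme = build_binning_scheme(
        panel["maf_afr"], panel["maf_eur"], n_common_bins=config.n_common_bins
    )
    bin_idx, bin_summary = assign_bins(panel, scheme, eur_common_only=True)
    occupied = bin_summary["bin"].to_numpy()
    # annotation columns restricted to occupied bins (empty columns are collinear)
    full = build_annotation_matrix(bin_idx, scheme.n_bins)
    annot = full[:, occupied]
    logger.info(
        "condition w=%.2f: %d SNPs, %d occupied bins", true_w, len(panel), len(occupied)
    )

    rows = []
    for rep in range(config.n_replicates):
        t0 = time.time()
        rep_seeds = _child_seeds(int(seeds[2 + rep]), 2 * gen.n_traits)
        if config.mode == "chi2":
            tables = _chi2_tables(panel, gen, annot, occupied, bin_summary, bin_idx, rep_seeds)
            fr = fitmod.fit_joint(
                tables,
                seed=int(rep_seeds[0]),
                de_popsize=config.de_popsize,
                de_maxiter=config.de_maxiter,
            )
        else:
            causal_only = config.mode == "oracle_causal_threshold"
            tables, snp_data = _oracle_tables(
                panel, gen, bin_summary, bin_idx, rep_seeds, causal_only
            )
            fr = fitmod.fit_joint(
                tables,
                seed=int(rep_seeds[0]),
                moment_form="mean_transform" if causal_only else "bin_mean",
                pmix_threshold=gen.plateau_T if causal_only else None,
                snp_data=snp_data if causal_only else None,
                de_popsize=config.de_popsize,
                de_maxiter=config.de_maxiter,
            )
        rows.append(
            {
                "true_w": true_w,
                "true_alpha": gen.alpha_true,
                "replicate": rep,
                "w_hat": fr.w,
                "alpha_hat": fr.alpha,
                "scaled_mse": fr.scaled_mse,
                "at_bounds": fr.at_bounds,
            }
        )
        logger.info(
            "  rep %d: w_hat=%.3f alpha_hat=%.3f (%.1fs)",
            rep, fr.w, fr.alpha, time.time() - t0,
        )
    return pd.DataFrame(rows)


def summarize_study(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and normal 95% CI of the estimates per condition."""
    rows = []
    for w, grp in results.groupby("true_w"):
        for param, col in (("w", "w_hat"), ("alpha", "alpha_hat")):
            vals = grp[col].to_numpy()
            m = float(vals.mean())
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            rows.append(
                {
                    "true_w": w,
                    "param": param,
                    "mean": m,
                    "se": se,
                    "ci_lo": m - 1.96 * se,
                    "ci_hi": m + 1.96 * se,
                    "n_replicates": len(vals),
                }
            )
    return pd.DataFrame(rows)


def run_simulation_study(config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every configured condition; returns (replicate table, summary)."""
    parts = [run_condition(config, w) for w in config.true_w_values]
    results = pd.concat(parts, ignore_index=True)
    results.attrs["config_hash"] = config.config_hash()
    summary = summarize_study(results)
    summary.attrs["config_hash"] = config.config_hash()
    return results, summary


def write_study_report(results: pd.DataFrame, summary: pd.DataFrame,
                       config: StudyConfig, out_dir) -> None:
    """Machine-readable tables + a short human-readable summary."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "study_replicates.tsv", sep="\t", index=False,
                   float_format="%.10g")
    summary.to_csv(out / "study_summary.tsv", sep="\t", index=False,
                   float_format="%.10g")
    config.save(out / "study_config.yaml")
    lines = [f"simulation study (mode={config.mode}, config {config.config_hash()})"]
    if summary.empty:
        lines.append("no results")
    for _, r in summary.iterrows():
        lines.append(
            f"true w={r['true_w']:.2f}: mean {r['param']}_hat = {r['mean']:.3f} "
            f"(95% CI {r['ci_lo']:.3f}..{r['ci_hi']:.3f}, {int(r['n_replicates'])} reps)"
        )
    (out / "study_report.txt").write_text("\n".join(lines) + "\n")


def report_figures(summary: pd.DataFrame, out_dir) -> list:
    """Estimate-with-CI panels per parameter (one file per parameter)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for param in summary["param"].unique():
        sub = summary[summary["param"] == param]
        figure, ax = plt.subplots(figsize=(4, 3))
        ax.errorbar(
            sub["true_w"], sub["mean"],
            yerr=1.96 * sub["se"], fmt="o", capsize=3,
        )
        if param == "w":
            ax.plot(sub["true_w"], sub["true_w"], "r--", lw=1)
        ax.set_xlabel("true w")
        ax.set_ylabel(f"mean estimated {param}")
        figure.tight_layout()
        path = out / f"study_{param}.png"
        figure.savefig(path, dpi=120)
        plt.close(figure)
        paths.append(path)
    return paths
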