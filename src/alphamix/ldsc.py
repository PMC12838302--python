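"""Bin-wise per-allele effect-size variance estimation.

A simplified stratified LD-score regression: GWAS chi-square statistics
are regressed on annotation LD scores,

    E[chi2_i] = 1 + N * sum_d tau_d * l_{i,d},

where the annotations are disjoint bivariate MAF-bin indicators.  In the
unlinked regime (the simulator produces no LD) the LD score of an
annotation reduces to its indicator, and the regression recovers the
mean per-SNP heritability of each bin.  Per-SNP heritability is
converted to per-allele effect-size variance by dividing by the
Hardy-Weinberg genotype variance 2*pE*(1-pE), and averaged per bin.

An oracle route computes bin means of the true squared effects instead,
for validating the estimation stage.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def build_annotation_matrix(bin_idx, n_bins: int) -> np.ndarray:
    """Disjoint indicator matrix (M x D) from per-SNP bivariate bin indices.

    SNPs with bin index -1 (excluded) get an all-zero row.
    """
    bin_idx = np.asarray(bin_idx)
    annot = np.zeros((len(bin_idx), n_bins))
    ok = bin_idx >= 0
    annot[np.nonzero(ok)[0], bin_idx[ok]] = 1.0
    return annot


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify identical column pairs for the error message
        dupes = []
        for i in range(design.shape[1]):
            for j in range(i + 1, design.shape[1]):
                if np.array_equal(design[:, i], design[:, j]):
                    dupes.append((names[i], names[j]))
        raise ValueError(
            f"rank-deficient annotation design (rank {rank} < {design.shape[1]}); "
            f"collinear columns: {dupes if dupes else 'not a simple duplication'}"
        )


def fit_stratified_ldsc(
    chi2,
    ld_scores: np.ndarray,
    n: int,
    free_intercept: bool = True,
    weights=None,
    annot_names: list[str] | None = None,
):
    """Weighted least-squares regression of chi2 on N * LD scores.

    ``chi2`` may be a vector (one trait) or an (M, T) matrix — the design
    factorization is shared across traits.  Returns ``(tau, intercept)``
    with ``tau`` of shape (D,) or (D, T).  The intercept is free by
    default (standard LD-score regression behavior) or fixed at 1.

    In unlinked mode ``ld_scores`` is simply the annotation indicator
    matrix; per-SNP weights default to 1 there (the usual
    heteroskedasticity weights are near-constant without LD) but a
    weight vector is accepted for LD-aware use.
    """
    chi2 = np.asarray(chi2, dtype=float)
    ell = np.asarray(ld_scores, dtype=float)
    if n <= 0:
        raise ValueError("sample size must be positive")
    one_trait = chi2.ndim == 1
    Y = chi2[:, None] if one_trait else chi2
    names = annot_names or [f"annot_{d}" for d in range(ell.shape[1])]
    X = n * ell
    if free_intercept:
        X = np.column_stack([np.ones(len(ell)), X])
        names = ["intercept"] + list(names)
    else:
        Y = Y - 1.0
    if weights is not None:
        sw = np.sqrt(np.asarray(weights, dtype=float))[:, None]
        X = X * sw
        Y = Y * sw
    _check_rank(X, names)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    if free_intercept:
        intercept, tau = coef[0], coef[1:]
    else:
        intercept, tau = np.ones(Y.shape[1]), coef
    if one_trait:
        return tau[:, 0], float(intercept[0])
    return tau, intercept


def per_allele_variance(tau, annot: np.ndarray, pE) -> np.ndarray:
    """Per-SNP per-allele effect variance from annotation coefficients.

    h2_i = sum_d a_d(i) tau_d; beta2_i = h2_i / (2 pE_i (1 - pE_i)).
    Negative values are legitimate sampling outcomes and are propagated.
    """
    pE = np.asarray(pE, dtype=float)
    if np.any(pE <= 0.0) or np.any(pE > 0.5):
        raise ValueError("pE must lie in (0, 0.5]")
    h2 = np.asarray(annot, dtype=float) @ np.asarray(tau, dtype=float)
    het = 2.0 * pE * (1.0 - pE)
    return h2 / (het if h2.ndim == 1 else het[:, None])


def bin_mean_variance(beta2, bin_idx, bin_summary: pd.DataFrame,
                      trait: str = "trait") -> pd.DataFrame:
    """Unweighted mean of per-SNP beta2 within each bivariate bin.

    Returns a bin-variance table (columns ``trait, bin, n, mean_pA,
    mean_pE, beta2_hat``); bins absent from ``bin_summary`` (empty) are
    excluded.  Negative means are retained, never truncated.
    """
    beta2 = np.asarray(beta2, dtype=float)
    bin_idx = np.asarray(bin_idx)
    rows = []
    for _, b in bin_summary.iterrows():
        mask = bin_idx == b["bin"]
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"bin {b['bin']} is empty; excluded from the table")
            continue
        rows.append(
            (trait, int(b["bin"]), n, b["mean_pA"], b["mean_pE"], float(beta2[mask].mean()))
        )
    return pd.DataFrame(
        rows, columns=["trait", "bin", "n", "mean_pA", "mean_pE", "beta2_hat"]
    )


def oracle_bin_variance(
    panel: pd.DataFrame,
    bin_idx,
    bin_summary: pd.DataFrame,
    causal_only: bool = False,
    trait: str = "trait",
) -> pd.DataFrame:
    """Bin means of the true squared per-allele effects.

    With ``causal_only`` the mean (and the bin's count and mean MAFs) are
    restricted to causal SNPs; bins without causal SNPs are excluded.
    """
    beta = panel["beta"].to_numpy(dtype=float)
    bin_idx = np.asarray(bin_idx)
    pA = panel["maf_afr"].to_numpy(dtype=float)
    pE = panel["maf_eur"].to_numpy(dtype=float)
    rows = []
    for _, b in bin_summary.iterrows():
        mask = bin_idx == b["bin"]
        if causal_only:
            mask = mask & (beta != 0.0)
        n = int(mask.sum())
        if n == 0:
            continue
        rows.append(
            (
                trait,
                int(b["bin"]),
                n,
                float(pA[mask].mean()),
                float(pE[mask].mean()),
                float((beta[mask] ** 2).mean()),
            )
        )
    return pd.DataFrame(
        rows, columns=["trait", "bin", "n", "mean_pA", "mean_pE", "beta2_hat"]
    )


def normalize_table(table: pd.DataFrame, common_only: bool = True) -> pd.DataFrame:
    """Scale a trait's bin means by its SNP-weighted mean over common bins.

    The normalizer is the mean per-allele variance over all SNPs with
    pE > 0.05 (SNP-count-weighted mean of the bin means), so that
    normalized values are comparable across traits.
    """
    t = table.copy()
    sel = t["mean_pE"] > 0.05 if common_only else np.ones(len(t), dtype=bool)
    norm = np.average(t.loc[sel, "beta2_hat"], weights=t.loc[sel, "n"])
    if norm <= 0:
        raise ValueError("non-positive normalizer for trait table")
    t["beta2_hat"] = t["beta2_hat"] / norm
    return t


def normalize_and_meta(
    tables: dict[str, pd.DataFrame],
    ses: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Cross-trait combination of normalized bin means.

    Each trait's table is normalized (see :func:`normalize_table`; traits
    with a non-positive normalizer are excluded with a warning), then
    each bin is combined across traits — by DerSimonian-Laird
    random-effects meta-analysis when per-bin standard errors are
    supplied (``ses``: trait -> DataFrame with columns bin, se, on the
    normalized scale), else by the plain mean with the empirical
    between-trait variance.
    """
    if len(tables) < 2:
        raise ValueError("cross-trait combination requires at least two traits")
    normed = {}
    for trait, tab in tables.items():
        try:
            normed[trait] = normalize_table(tab)
        except ValueError:
            warnings.warn(f"trait {trait!r} excluded: non-positive normalizer")
    long = pd.concat(normed.values(), ignore_index=True)
    rows = []
    for b, grp in long.groupby("bin"):
        vals = grp["beta2_hat"].to_numpy()
        if ses is not None:
            from .meta import meta_analyze

            se = np.concatenate(
                [
                    ses[t].set_index("bin").loc[[b], "se"].to_numpy()
                    for t in normed
                    if b in set(ses[t]["bin"])
                ]
            )
            m = meta_analyze(vals, se)
            rows.append((b, len(vals), m.re_estimate, m.re_se, m.tau2))
        else:
            rows.append(
                (
                    b,
                    len(vals),
                    float(vals.mean()),
                    float(vals.std(ddof=1) / np.sqrt(len(vals))),
                    float(vals.var(ddof=1)),
                )
            )
    return pd.DataFrame(
        rows, columns=["bin", "n_traits", "combined", "se", "between_trait_var"]
    )
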