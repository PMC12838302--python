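"""Generative model for joint-ancestry MAF panels, labels, effects and GWAS z-scores.

The simulator emulates the statistical structure the estimation stages
assume, without any population-genetic forward simulation or LD:

* an ancestral frequency ``q0`` is drawn from a density proportional to
  1/q on a truncated interval (the neutral site-frequency-spectrum
  shape), and present-day African / European frequencies are drawn from
  a Balding-Nichols Beta distribution around ``q0`` with drift
  parameters ``F`` — a small ``F`` for Africa and a larger one for
  Europe mimics the out-of-Africa bottleneck distortion of the European
  spectrum while keeping the two folded MAFs positively correlated;
* binary non-synonymous labels follow a logistic model in log(pmix);
* sparse per-allele causal effects have variance proportional to
  ``[q(1-q)]^alpha`` with ``q = max(T, pmix)`` — the plateau threshold
  ``T`` caps the growth of per-allele variance at low MAF — rescaled so
  the genetic variance equals a target heritability;
* marginal-association Z-scores are produced either directly from the
  non-centrality of unlinked SNPs or from an explicit genotype matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import compute_pmix, floor_maf

#: Truncation of the ancestral 1/q frequency density.
Q0_MIN = 5e-4
#: Guard band for simulated frequencies before folding.
FREQ_CLIP = 1e-6


@dataclass
class GenerativeConfig:
    """Parameters of the generative model (study conditions).

    Defaults are a desk-scale rendering of a large biobank simulation
    design (M=5,907,305 common SNPs, N=337,448, n_causal=10,000,
    h2=0.5), scaled so the *estimator* operates in the same statistical
    regime: with s = M_desk/M_full, the sample size N_full*sqrt(s)
    preserves the per-bin relative standard error of the bin-wise
    variance moments (SE(tau_k)/tau ~ M*sqrt(2/n_k)/(N*h2)), and keeping
    n_causal at 10,000 preserves the full design's per-bin causal count
    (~83 over 120 bivariate bins), the other dominant noise source.
    """

    n_snps: int = 50_000
    n_traits: int = 25
    gwas_n: int = 31_047
    h2: float = 0.5
    w_true: float = 0.95
    alpha_true: float = -0.38
    plateau_T: float = 0.005
    n_causal: int = 10_000
    drift_afr: float = 0.01
    drift_eur: float = 0.12
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.h2 < 1):
            raise ValueError(f"h2 must lie in (0, 1), got {self.h2}")
        if not (0 < self.plateau_T < 0.5):
            raise ValueError(f"plateau_T must lie in (0, 0.5), got {self.plateau_T}")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        for name in ("n_snps", "n_traits", "gwas_n", "n_causal"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")


def _check_drift(name: str, value: float) -> None:
    if not np.isfinite(value) or not (0.0 <= value < 1.0):
        raise ValueError(f"{name} must be finite and in [0, 1), got {value}")


def sample_ancestral_freq(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ancestral frequencies from the normalized 1/q density.

    The density is proportional to 1/q on [Q0_MIN, 1 - Q0_MIN]; inverse-CDF
    sampling gives ``q = a * (b/a)**u`` for uniform ``u``.
    """
    a, b = Q0_MIN, 1.0 - Q0_MIN
    u = rng.uniform(size=n)
    return a * (b / a) ** u


def simulate_maf_panel(
    n_snps: int,
    drift_afr: float = 0.01,
    drift_eur: float = 0.12,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a panel of SNPs with correlated African/European MAFs.

    Population frequencies follow a Balding-Nichols distribution
    ``Beta(q0*(1-F)/F, (1-q0)*(1-F)/F)`` (mean q0, variance q0(1-q0)F)
    around a shared ancestral frequency; ``F = 0`` is the no-drift limit
    in which both populations inherit ``q0`` exactly.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    _check_drift("drift_afr", drift_afr)
    _check_drift("drift_eur", drift_eur)
    rng = np.random.default_rng(seed)
    q0 = sample_ancestral_freq(n_snps, rng)

    def drifted(F: float) -> np.ndarray:
        if F == 0.0:
            return q0.copy()
        k = (1.0 - F) / F
        return rng.beta(q0 * k, (1.0 - q0) * k)

    freq_afr = np.clip(drifted(drift_afr), FREQ_CLIP, 1.0 - FREQ_CLIP)
    freq_eur = np.clip(drifted(drift_eur), FREQ_CLIP, 1.0 - FREQ_CLIP)
    return pd.DataFrame(
        {
            "snp_id": [f"snp_{i}" for i in range(n_snps)],
            "pos_index": np.arange(n_snps),
            "freq_afr": freq_afr,
            "freq_eur": freq_eur,
            "maf_afr": np.minimum(freq_afr, 1.0 - freq_afr),
            "maf_eur": np.minimum(freq_eur, 1.0 - freq_eur),
        }
    )


def simulate_common_panel(
    n_snps: int,
    drift_afr: float = 0.01,
    drift_eur: float = 0.12,
    seed: int = 0,
    min_eur_maf: float = 0.05,
) -> pd.DataFrame:
    """Panel conditioned on European MAF >= ``min_eur_maf``.

    GWAS analyses of heritability are typically restricted to SNPs common
    in the GWAS population; this rejection-samples the generative panel
    until ``n_snps`` such SNPs are collected.
    """
    chunks: list[pd.DataFrame] = []
    got = 0
    for attempt in range(200):
        chunk = simulate_maf_panel(
            int(n_snps * 1.5) + 1000, drift_afr, drift_eur, seed=seed + 7919 * attempt
        )
        chunk = chunk[chunk["maf_eur"] >= min_eur_maf]
        chunks.append(chunk)
        got += len(chunk)
        if got >= n_snps:
            break
    else:  # pragma: no cover - would need pathological drift settings
        raise RuntimeError("failed to collect enough common SNPs")
    panel = pd.concat(chunks, ignore_index=True).iloc[:n_snps].copy()
    panel["snp_id"] = [f"snp_{i}" for i in range(n_snps)]
    panel["pos_index"] = np.arange(n_snps)
    return panel.reset_index(drop=True)


def label_nonsynonymous(
    panel: pd.DataFrame,
    w: float,
    gamma: float = -0.13,
    mu: float = -5.0,
    maf_floor: float = 0.002,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw Bernoulli non-synonymous labels from the logistic pmix model.

    Label probability is ``expit(mu + gamma * log(pmix))`` where pmix is
    computed from MAFs floored at ``maf_floor``.  Default slope and
    intercept give a weak negative MAF dependence and an overall label
    rate near 1%, the regime of genome-wide coding annotation.
    """
    if not (0.0 <= w <= 1.0):
        raise ValueError("generative w must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pmix = compute_pmix(
        floor_maf(panel["maf_afr"], maf_floor),
        floor_maf(panel["maf_eur"], maf_floor),
        w,
    )
    from scipy.special import expit

    prob = expit(mu + gamma * np.log(pmix))
    out = panel.copy()
    out["nonsyn"] = (rng.uniform(size=len(panel)) < prob).astype(int)
    return out


def generative_pmix(panel: pd.DataFrame, config: GenerativeConfig) -> np.ndarray:
    """Thresholded mixture frequency ``max(T, w*pA + (1-w)*pE)`` of the generative model."""
    pmix = compute_pmix(panel["maf_afr"], panel["maf_eur"], config.w_true)
    return np.maximum(config.plateau_T, pmix)


def simulate_causal_effects(
    panel: pd.DataFrame,
    config: GenerativeConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw sparse per-allele causal effects under the MAF-mixture variance law.

    ``n_causal`` SNPs (uniformly chosen) receive
    ``beta ~ Normal(0, [q(1-q)]^alpha_true)`` with ``q`` the thresholded
    mixture frequency; all effects are then rescaled by one constant so
    the genetic variance ``sum 2 p (1-p) beta^2`` (p = European GWAS
    frequency, phenotypic variance 1) equals ``h2`` exactly.  The
    proportionality constant of the variance law is irrelevant because
    this rescaling absorbs it.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    q = generative_pmix(panel, config)
    var = (q * (1.0 - q)) ** config.alpha_true
    idx = rng.choice(len(panel), size=config.n_causal, replace=False)
    beta = np.zeros(len(panel))
    beta[idx] = rng.normal(0.0, np.sqrt(var[idx]))
    p = panel["freq_eur"].to_numpy(dtype=float)
    gvar = np.sum(2.0 * p * (1.0 - p) * beta**2)
    if gvar <= 0.0:
        raise ValueError("degenerate rescaling: simulated genetic variance is zero")
    beta *= np.sqrt(config.h2 / gvar)
    out = panel.copy()
    out["beta"] = beta
    return out


def simulate_sumstats_direct(
    panel: pd.DataFrame,
    gwas_n: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Marginal-association Z-scores for unlinked SNPs, without genotypes.

    For an unlinked SNP with per-allele effect beta and GWAS-population
    frequency p, the marginal Z-score is
    ``z = sqrt(N) * beta * sqrt(2 p (1-p)) + e`` with standard normal
    noise (phenotypic variance 1); null SNPs then have E[chi2] = 1.
    """
    rng = np.random.default_rng(seed)
    beta = panel["beta"].to_numpy(dtype=float)
    p = panel["freq_eur"].to_numpy(dtype=float)
    mean_z = np.sqrt(gwas_n) * beta * np.sqrt(2.0 * p * (1.0 - p))
    z = mean_z + rng.standard_normal(len(panel))
    return pd.DataFrame(
        {
            "snp_id": panel["snp_id"].to_numpy(),
            "z": z,
            "n": gwas_n,
            "chi2": z**2,
        }
    )


def simulate_genotypes_explicit(
    panel: pd.DataFrame,
    gwas_n: int,
    seed: int = 0,
    h2: float | None = None,
    max_elements: int = 200_000_000,
) -> pd.DataFrame:
    """Z-scores from an explicit additive model Y = X beta + eps (validation mode).

    Genotypes are Binomial(2, p) per SNP (Hardy-Weinberg, no LD); the
    residual variance is ``1 - h2`` with ``h2`` the target genetic
    variance of the panel's effects (inferred from the effects if not
    given).  Per-SNP marginal least-squares association yields z.
    Intended for small cross-checks of the direct mode: panels whose
    genotype matrix exceeds ``max_elements`` are refused.
    """
    if gwas_n * len(panel) > max_elements:
        raise ValueError(
            f"genotype matrix of {gwas_n} x {len(panel)} exceeds the size cap"
        )
    rng = np.random.default_rng(seed)
    beta = panel["beta"].to_numpy(dtype=float)
    p = panel["freq_eur"].to_numpy(dtype=float)
    if h2 is None:
        h2 = float(np.sum(2.0 * p * (1.0 - p) * beta**2))
    X = rng.binomial(2, p[None, :], size=(gwas_n, len(panel))).astype(np.float64)
    y = X @ beta + rng.normal(0.0, np.sqrt(max(1.0 - h2, 0.0)), size=gwas_n)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    sxy = Xc.T @ yc
    syy = float(yc @ yc)
    r = sxy / np.sqrt(np.maximum(sxx * syy, 1e-300))
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    z = r * np.sqrt(gwas_n - 2) / np.sqrt(1.0 - r**2)
    return pd.DataFrame(
        {
            "snp_id": panel["snp_id"].to_numpy(),
            "z": z,
            "n": gwas_n,
            "chi2": z**2,
        }
    )
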