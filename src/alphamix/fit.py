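"""GMM estimation of the MAF-mixture effect-size variance model.

The model predicts the mean per-allele effect-size variance of a
bivariate MAF bin k for trait t as

    E[beta_t^2 | bin k] = (sigma_t^2 / 2) * [pmix_k (1 - pmix_k)]^alpha,
    pmix_k = w * mean_pA_k + (1 - w) * mean_pE_k,

and estimates (w, alpha) by minimizing the SNP-count-weighted squared
deviation between predictions and bin-wise variance estimates, summed
over traits.  The per-trait scale sigma_t^2 is a quadratic nuisance with
a closed-form minimizer, so the numerical search is 2-dimensional:
bounded differential evolution over w in [-0.5, 1.5] and alpha in
[-1.5, 1.5], followed by a local polish.

Two moment forms are supported: the default transforms the bin-mean
mixture frequency ("bin_mean"); the alternative averages the per-SNP
transform within each bin ("mean_transform"), optionally thresholding
per-SNP pmix at a plateau value T — the form under which the estimator
is unbiased when the generative model itself plateaus at T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .binning import PMIX_CLIP

W_BOUNDS = (-0.5, 1.5)
ALPHA_BOUNDS = (-1.5, 1.5)

_REQUIRED_COLS = {"bin", "n", "mean_pA", "mean_pE", "beta2_hat"}


@dataclass
class SnpLevelData:
    """Per-SNP inputs for the mean-of-transform moment form (one trait)."""

    pA: np.ndarray
    pE: np.ndarray
    bin_idx: np.ndarray  # aligned with the trait's table rows via bin ids


@dataclass
class MomentData:
    """Aligned per-trait arrays extracted from bin-variance tables."""

    n: list[np.ndarray]
    beta2: list[np.ndarray]
    mean_pA: list[np.ndarray]
    mean_pE: list[np.ndarray]
    bins: list[np.ndarray]
    snp_data: list[SnpLevelData] | None = None
    _snp_rows: list[np.ndarray] | None = None  # SNP -> table row, cached
    _stacked: dict | None = None               # flat cross-trait arrays, cached

    @property
    def n_traits(self) -> int:
        return len(self.n)

    def snp_rows(self, t: int) -> np.ndarray:
        if self._snp_rows is None:
            self._snp_rows = [None] * self.n_traits
        if self._snp_rows[t] is None:
            lookup = {b: i for i, b in enumerate(self.bins[t])}
            rows = np.array([lookup.get(b, -1) for b in self.snp_data[t].bin_idx])
            if np.any(np.bincount(rows[rows >= 0], minlength=len(self.bins[t])) == 0):
                raise ValueError("snp_data covers no SNPs for some table bin")
            self._snp_rows[t] = rows
        return self._snp_rows[t]

    def stacked(self) -> dict:
        """Flat concatenation across traits for vectorized loss evaluation."""
        if self._stacked is None:
            sizes = [len(x) for x in self.n]
            trait_id = np.repeat(np.arange(self.n_traits), sizes)
            st = {
                "trait_id": trait_id,
                "n": np.concatenate(self.n),
                "beta2": np.concatenate(self.beta2),
                "mean_pA": np.concatenate(self.mean_pA),
                "mean_pE": np.concatenate(self.mean_pE),
                "offsets": np.concatenate([[0], np.cumsum(sizes)]),
            }
            if self.snp_data is not None:
                rows = [self.snp_rows(t) for t in range(self.n_traits)]
                grows = np.concatenate(
                    [r + st["offsets"][t] for t, r in enumerate(rows)]
                )
                keep = np.concatenate([r >= 0 for r in rows])
                st["snp_pA"] = np.concatenate([s.pA for s in self.snp_data])[keep]
                st["snp_pE"] = np.concatenate([s.pE for s in self.snp_data])[keep]
                st["snp_row"] = grows[keep]
                st["snp_counts"] = np.bincount(st["snp_row"], minlength=len(st["n"]))
            self._stacked = st
        return self._stacked


def _prepare(tables, snp_data=None) -> MomentData:
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    data = MomentData(n=[], beta2=[], mean_pA=[], mean_pE=[], bins=[], snp_data=snp_data)
    for t in tables:
        missing = _REQUIRED_COLS - set(t.columns)
        if missing:
            raise ValueError(f"bin-variance table is missing columns {sorted(missing)}")
        if (t["n"] <= 0).any():
            raise ValueError("every included bin must have n > 0")
        data.n.append(t["n"].to_numpy(dtype=float))
        data.beta2.append(t["beta2_hat"].to_numpy(dtype=float))
        data.mean_pA.append(t["mean_pA"].to_numpy(dtype=float))
        data.mean_pE.append(t["mean_pE"].to_numpy(dtype=float))
        data.bins.append(t["bin"].to_numpy())
    if snp_data is not None and len(snp_data) != data.n_traits:
        raise ValueError("snp_data must provide one entry per trait")
    return data


def _bin_transform(
    data: MomentData,
    t: int,
    w: float,
    alpha: float,
    moment_form: str,
    pmix_threshold: float | None,
) -> np.ndarray:
    """g_k = model MAF transform per bin for trait t at (w, alpha)."""
    if moment_form == "bin_mean":
        pm = w * data.mean_pA[t] + (1.0 - w) * data.mean_pE[t]
        if pmix_threshold is not None:
            pm = np.maximum(pm, pmix_threshold)
        pm = np.clip(pm, *PMIX_CLIP)
        return (pm * (1.0 - pm)) ** alpha
    if moment_form == "mean_transform":
        sd = data.snp_data[t]
        pm = w * sd.pA + (1.0 - w) * sd.pE
        if pmix_threshold is not None:
            pm = np.maximum(pm, pmix_threshold)
        pm = np.clip(pm, *PMIX_CLIP)
        tr = (pm * (1.0 - pm)) ** alpha
        # mean of the transform within each table bin
        rows = data.snp_rows(t)
        ok = rows >= 0
        nbins = len(data.bins[t])
        sums = np.bincount(rows[ok], weights=tr[ok], minlength=nbins)
        counts = np.bincount(rows[ok], minlength=nbins)
        return sums / counts
    raise ValueError(f"unknown moment_form {moment_form!r}")


def predict_bin_variance(w: float, alpha: float, sigma2: float,
                         mean_pA, mean_pE) -> np.ndarray:
    """Model-predicted mean per-allele effect variance per bin."""
    pm = np.clip(
        w * np.asarray(mean_pA, dtype=float) + (1 - w) * np.asarray(mean_pE, dtype=float),
        *PMIX_CLIP,
    )
    return sigma2 / 2.0 * (pm * (1.0 - pm)) ** alpha


def analytic_sigma_g(n, beta2, g) -> float:
    """Closed-form minimizer of the quadratic-in-sigma bin loss.

    sigma^2 = 2 * sum_k n_k beta2_k g_k / sum_k n_k g_k^2; may be
    negative when the bin means are predominantly negative.
    """
    denom = float(np.sum(n * g**2))
    if denom == 0.0:
        raise ValueError("all bin transforms are zero; sigma is undefined")
    return 2.0 * float(np.sum(n * beta2 * g)) / denom


def analytic_sigma(w: float, alpha: float, table: pd.DataFrame,
                   pmix_threshold: float | None = None) -> float:
    """Closed-form sigma^2 for one trait's table at fixed (w, alpha)."""
    data = _prepare(table)
    g = _bin_transform(data, 0, w, alpha, "bin_mean", pmix_threshold)
    return analytic_sigma_g(data.n[0], data.beta2[0], g)


def gmm_loss(w: float, alpha: float, sigmas, tables,
             pmix_threshold: float | None = None) -> float:
    """SNP-count-weighted squared-moment loss summed over traits and bins."""
    data = tables if isinstance(tables, MomentData) else _prepare(tables)
    sigmas = np.atleast_1d(np.asarray(sigmas, dtype=float))
    if sigmas.size != data.n_traits:
        raise ValueError("one sigma^2 per trait is required")
    total = 0.0
    for t in range(data.n_traits):
        g = _bin_transform(data, t, w, alpha, "bin_mean", pmix_threshold)
        resid = sigmas[t] / 2.0 * g - data.beta2[t]
        total += float(np.sum(data.n[t] * resid**2))
    return total


def _profiled_loss(data: MomentData, w: float, alpha: float,
                   moment_form: str, pmix_threshold) -> tuple[float, np.ndarray]:
    """Loss with sigma^2 eliminated analytically per trait (vectorized)."""
    st = data.stacked()
    if moment_form == "bin_mean":
        pm = w * st["mean_pA"] + (1.0 - w) * st["mean_pE"]
        if pmix_threshold is not None:
            pm = np.maximum(pm, pmix_threshold)
        pm = np.clip(pm, *PMIX_CLIP)
        g = (pm * (1.0 - pm)) ** alpha
    elif moment_form == "mean_transform":
        pm = w * st["snp_pA"] + (1.0 - w) * st["snp_pE"]
        if pmix_threshold is not None:
            pm = np.maximum(pm, pmix_threshold)
        pm = np.clip(pm, *PMIX_CLIP)
        tr = (pm * (1.0 - pm)) ** alpha
        g = np.bincount(st["snp_row"], weights=tr, minlength=len(st["n"]))
        g = g / st["snp_counts"]
    else:
        raise ValueError(f"unknown moment_form {moment_form!r}")
    nn, bb, tid = st["n"], st["beta2"], st["trait_id"]
    num = np.bincount(tid, weights=nn * bb * g, minlength=data.n_traits)
    den = np.bincount(tid, weights=nn * g * g, minlength=data.n_traits)
    if np.any(den == 0.0):
        raise ValueError("all bin transforms are zero; sigma is undefined")
    sigmas = 2.0 * num / den
    resid = sigmas[tid] / 2.0 * g - bb
    return float(np.sum(nn * resid * resid)), sigmas


def null_loss(data: MomentData) -> float:
    """Loss of the no-MAF-dependence null (alpha = 0, best sigma per trait)."""
    total = 0.0
    for t in range(data.n_traits):
        g = np.ones_like(data.beta2[t])
        s = analytic_sigma_g(data.n[t], data.beta2[t], g)
        total += float(np.sum(data.n[t] * (s / 2.0 - data.beta2[t]) ** 2))
    return total


@dataclass
class FitResult:
    """Fitted MAF-mixture parameters for one or more traits."""

    w: float
    alpha: float
    sigma2: np.ndarray          # per-trait scale parameters
    loss: float
    scaled_mse: float           # loss scaled so the alpha=0 null is 1
    residuals: list[np.ndarray] = field(repr=False, default_factory=list)
    at_bounds: bool = False
    non_identifiable: bool = False
    n_traits: int = 1

    @property
    def params(self) -> dict:
        return {"w": self.w, "alpha_mix": self.alpha, "sigma_g2": self.sigma2.tolist()}


def fit_joint(
    tables,
    bounds: tuple = (W_BOUNDS, ALPHA_BOUNDS),
    seed: int = 0,
    moment_form: str = "bin_mean",
    pmix_threshold: float | None = None,
    snp_data: list[SnpLevelData] | None = None,
    de_popsize: int = 30,
    de_maxiter: int = 200,
) -> FitResult:
    """Global fit of a single (w, alpha) across traits.

    Differential evolution over the bounded 2-D parameter space with the
    per-trait sigma^2 profiled out analytically at every evaluation,
    followed by the optimizer's local polish.  A coarse grid scan flags
    non-identifiability (distant parameter points with numerically equal
    loss); in that case the reported optimum is the candidate with the
    smallest |w - 0.5|.
    """
    data = _prepare(tables, snp_data=snp_data)

    def objective(x) -> float:
        return _profiled_loss(data, x[0], x[1], moment_form, pmix_threshold)[0]

    res = optimize.differential_evolution(
        objective,
        bounds=list(bounds),
        seed=seed,
        popsize=de_popsize,
        maxiter=de_maxiter,
        polish=True,
    )
    w_hat, a_hat = float(res.x[0]), float(res.x[1])
    best = float(res.fun)

    # coarse non-identifiability scan
    non_ident = False
    wg = np.linspace(bounds[0][0], bounds[0][1], 21)
    ag = np.linspace(bounds[1][0], bounds[1][1], 13)
    for wv in wg:
        for av in ag:
            if abs(wv - w_hat) < 0.1 and abs(av - a_hat) < 0.1:
                continue
            lv = objective((wv, av))
            if lv <= best * (1 + 1e-9) + 1e-30:
                loc = optimize.minimize(
                    objective, x0=(wv, av), bounds=list(bounds), method="L-BFGS-B"
                )
                if loc.fun <= best * (1 + 1e-9) + 1e-30 and (
                    abs(loc.x[0] - w_hat) > 0.05
                ):
                    non_ident = True
                    if abs(loc.x[0] - 0.5) < abs(w_hat - 0.5):
                        w_hat, a_hat, best = float(loc.x[0]), float(loc.x[1]), float(loc.fun)
    loss, sigmas = _profiled_loss(data, w_hat, a_hat, moment_form, pmix_threshold)
    resids = []
    for t in range(data.n_traits):
        g = _bin_transform(data, t, w_hat, a_hat, moment_form, pmix_threshold)
        resids.append(sigmas[t] / 2.0 * g - data.beta2[t])
    nl = null_loss(data)
    at_bounds = (
        min(w_hat - bounds[0][0], bounds[0][1] - w_hat) < 1e-6
        or min(a_hat - bounds[1][0], bounds[1][1] - a_hat) < 1e-6
    )
    return FitResult(
        w=w_hat,
        alpha=a_hat,
        sigma2=sigmas,
        loss=loss,
        scaled_mse=loss / nl if nl > 0 else np.nan,
        residuals=resids,
        at_bounds=at_bounds,
        non_identifiable=non_ident,
        n_traits=data.n_traits,
    )


def fit_per_trait(table, **kwargs) -> FitResult:
    """Single-trait fit: the joint fit with T = 1."""
    return fit_joint([table] if isinstance(table, pd.DataFrame) else table, **kwargs)


def fit_fixed_w(
    tables,
    w: float,
    alpha_bounds: tuple = ALPHA_BOUNDS,
    moment_form: str = "bin_mean",
    pmix_threshold: float | None = None,
    snp_data=None,
) -> FitResult:
    """Best alpha (and analytic sigmas) at a fixed mixture weight."""
    data = _prepare(tables, snp_data=snp_data)

    def objective(a: float) -> float:
        return _profiled_loss(data, w, a, moment_form, pmix_threshold)[0]

    res = optimize.minimize_scalar(
        objective, bounds=alpha_bounds, method="bounded", options={"xatol": 1e-8}
    )
    a_hat = float(res.x)
    loss, sigmas = _profiled_loss(data, w, a_hat, moment_form, pmix_threshold)
    nl = null_loss(data)
    return FitResult(
        w=w,
        alpha=a_hat,
        sigma2=sigmas,
        loss=loss,
        scaled_mse=loss / nl if nl > 0 else np.nan,
        n_traits=data.n_traits,
    )


def profile_alpha_over_w(
    tables,
    w_grid,
    moment_form: str = "bin_mean",
    pmix_threshold: float | None = None,
    snp_data=None,
) -> pd.DataFrame:
    """Best-fit alpha and scaled MSE as a function of the mixture weight.

    The scaled MSE divides the weighted loss by the loss of the
    no-MAF-dependence null (alpha = 0), so the null sits exactly at 1.
    """
    rows = []
    for w in np.asarray(w_grid, dtype=float):
        fr = fit_fixed_w(
            tables, w, moment_form=moment_form,
            pmix_threshold=pmix_threshold, snp_data=snp_data,
        )
        rows.append((w, fr.alpha, fr.scaled_mse, fr.loss))
    return pd.DataFrame(rows, columns=["w", "alpha_hat", "scaled_mse", "loss"])


def select_independent_traits(
    h2_z,
    nh2,
    rg2: np.ndarray,
    z_min: float = 6.0,
    nh2_min: float = 20_000.0,
    rg2_max: float = 0.1,
) -> list[int]:
    """Greedy selection of approximately independent, heritable traits.

    Filter to traits with heritability z-score > ``z_min`` and
    N*h2 > ``nh2_min``; then greedily accept traits in descending N*h2
    order, rejecting any candidate whose squared genetic correlation
    with an already-selected trait is >= ``rg2_max``.
    """
    h2_z = np.asarray(h2_z, dtype=float)
    nh2 = np.asarray(nh2, dtype=float)
    rg2 = np.asarray(rg2, dtype=float)
    if rg2.shape != (len(nh2), len(nh2)) or not np.allclose(rg2, rg2.T):
        raise ValueError("rg2 must be a symmetric trait-by-trait matrix")
    candidates = [i for i in range(len(nh2)) if h2_z[i] > z_min and nh2[i] > nh2_min]
    candidates.sort(key=lambda i: -nh2[i])
    selected: list[int] = []
    for i in candidates:
        if all(rg2[i, j] < rg2_max for j in selected):
            selected.append(i)
    return selected
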