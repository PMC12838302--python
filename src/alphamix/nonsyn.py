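"""Profile-likelihood logistic model for non-synonymous status.

The probability that a SNP is non-synonymous is modeled as

    logit P(Y = 1) = mu + gamma * log(pmix),      pmix = w*pA + (1-w)*pE,

with MAFs floored at a small value before mixing.  ``w`` is estimated by
profiling the likelihood: for each candidate ``w`` the nuisance
parameters (mu, gamma) are maximized out by a logistic fit, and the
resulting profile L(w) is maximized over a bounded interval.  Confidence
intervals and p-values for ``w`` come from the 1-df likelihood-ratio
statistic; non-nested single-ancestry models are compared with Vuong's
test and, across different SNP sets, a genomic block jackknife.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .binning import clamp_pmix, compute_pmix, floor_maf
from .jackknife import block_bounds, jackknife_se

#: 95% quantile of chi-square with 1 df; defines LRT confidence intervals.
LRT_CRIT_95 = 3.841458820694124
#: Reporting floor for p-values.
P_FLOOR = 1e-15

_MAX_ITER = 100
_GRAD_TOL = 1e-8
_RIDGE = 1e-10


class SeparationError(RuntimeError):
    """Raised when the two label classes are (quasi-)completely separated."""


@dataclass
class LogisticFit:
    """Maximum-likelihood fit of ``logit P = mu + gamma * x``."""

    mu: float
    gamma: float
    loglik: float
    n: int
    converged: bool
    se_mu: float = np.nan
    se_gamma: float = np.nan

    def per_obs_loglik(self, labels, x) -> np.ndarray:
        eta = self.mu + self.gamma * np.asarray(x, dtype=float)
        y = np.asarray(labels, dtype=float)
        # log p for y=1, log(1-p) for y=0, numerically stable
        return -np.logaddexp(0.0, -eta) * y - np.logaddexp(0.0, eta) * (1.0 - y)


def fit_logistic(labels, x, start: tuple[float, float] | None = None) -> LogisticFit:
    """Two-parameter logistic regression by iteratively reweighted least squares.

    Raises on degenerate input: a single label class, a constant
    predictor (slope unidentifiable), or complete separation.
    """
    y = np.asarray(labels, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("labels and predictor must be 1-D and aligned")
    if not np.all(np.isfinite(x)):
        raise ValueError("predictor contains non-finite values")
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        raise ValueError("both label classes must be present")
    if np.ptp(x) == 0.0:
        raise ValueError("constant predictor: slope is unidentifiable")

    # Center the predictor for conditioning; un-center at the end.
    xm = x.mean()
    xc = x - xm
    if start is not None:
        beta = np.array([start[0] + start[1] * xm, start[1]], dtype=float)
    else:
        beta = np.array([np.log(ybar / (1.0 - ybar)), 0.0])
    X = np.column_stack([np.ones_like(xc), xc])

    def loglik_of(b: np.ndarray) -> float:
        eta = X @ b
        return float(np.sum(-np.logaddexp(0.0, -eta) * y - np.logaddexp(0.0, eta) * (1 - y)))

    converged = False
    ll = loglik_of(beta)
    # relative gradient tolerance: gradient components scale with n
    gtol = _GRAD_TOL * max(1.0, len(y))
    for _ in range(_MAX_ITER):
        eta = X @ beta
        p = expit(eta)
        grad = X.T @ (y - p)
        if np.max(np.abs(grad)) < gtol:
            converged = True
            break
        W = p * (1.0 - p)
        info = (X * W[:, None]).T @ X
        info[np.diag_indices_from(info)] += _RIDGE
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise SeparationError("singular information matrix") from exc
        # step-halving line search guarantees monotone ascent (guards
        # against overshoot into the saturated region from a bad start)
        new_ll = loglik_of(beta + step)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            new_ll = loglik_of(beta + step)
            halvings += 1
        beta = beta + step
        ll = new_ll
        if np.max(np.abs(beta)) > 1e4:
            raise SeparationError("parameter divergence: complete separation")
    eta = X @ beta
    ll = float(np.sum(-np.logaddexp(0.0, -eta) * y - np.logaddexp(0.0, eta) * (1 - y)))
    if ll > -1e-6 * len(y):
        # an essentially perfect fit means the classes are separable
        raise SeparationError("complete separation: classes are perfectly split")
    if not converged:
        p_hat = expit(eta)
        if np.all((p_hat > 0.5) == (y == 1)) and np.max(np.abs(beta)) > 10.0:
            raise SeparationError("complete separation: classes are perfectly split")
    W = expit(eta) * (1.0 - expit(eta))
    info = (X * W[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        se_c = np.sqrt(np.diag(cov))
        # translate intercept SE back to the uncentered parameterization
        se_mu = float(np.sqrt(cov[0, 0] + xm**2 * cov[1, 1] - 2 * xm * cov[0, 1]))
        se_gamma = float(se_c[1])
    except np.linalg.LinAlgError:  # pragma: no cover
        se_mu = se_gamma = np.nan
    fit = LogisticFit(
        mu=float(beta[0] - beta[1] * xm),
        gamma=float(beta[1]),
        loglik=ll,
        n=len(y),
        converged=converged,
        se_mu=se_mu,
        se_gamma=se_gamma,
    )
    if not converged:
        warnings.warn("logistic fit did not converge within iteration limit")
    return fit


def fit_null_logistic(labels) -> LogisticFit:
    """Intercept-only fit (gamma = 0): mu = logit of the label mean."""
    y = np.asarray(labels, dtype=float)
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        raise ValueError("both label classes must be present")
    mu = float(np.log(ybar / (1.0 - ybar)))
    ll = float(len(y) * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar)))
    return LogisticFit(mu=mu, gamma=0.0, loglik=ll, n=len(y), converged=True)


def log_pmix(pA, pE, w: float, maf_floor: float = 0.002) -> np.ndarray:
    """log of the (floored, clamped) mixture frequency."""
    pm = compute_pmix(floor_maf(pA, maf_floor), floor_maf(pE, maf_floor), w)
    return np.log(clamp_pmix(pm))


def profile_loglik(
    labels, pA, pE, w: float, maf_floor: float = 0.002,
    start: tuple[float, float] | None = None,
) -> LogisticFit:
    """Logistic fit at fixed mixture weight w (nuisance mu, gamma maximized).

    At w = 1 (resp. 0) this is exactly the African-only (European-only)
    MAF model.
    """
    return fit_logistic(labels, log_pmix(pA, pE, w, maf_floor), start=start)


@dataclass
class ProfileCurve:
    """Profile log-likelihood of the mixture weight."""

    w_grid: np.ndarray
    loglik_at_w: np.ndarray
    gamma_at_w: np.ndarray
    mu_at_w: np.ndarray
    w_mle: float
    loglik_mle: float
    ci95: tuple[float, float]
    fit_mle: LogisticFit = field(repr=False, default=None)

    def lrt_stat(self, w0: float, labels=None, pA=None, pE=None,
                 maf_floor: float = 0.002) -> float:
        fit0 = profile_loglik(labels, pA, pE, w0, maf_floor)
        return 2.0 * (self.loglik_mle - fit0.loglik)

    def lrt_pvalue(self, w0: float, labels=None, pA=None, pE=None,
                   maf_floor: float = 0.002) -> float:
        stat = max(self.lrt_stat(w0, labels, pA, pE, maf_floor), 0.0)
        return float(stats.chi2.sf(stat, df=1))


def format_pvalue(p: float) -> str:
    """Report tiny p-values as a floor rather than a misleading exact number."""
    return "<1e-15" if p < P_FLOOR else f"{p:.3g}"


def maximize_profile(
    labels,
    pA,
    pE,
    maf_floor: float = 0.002,
    bounds: tuple[float, float] = (-0.5, 1.5),
    n_grid: int = 31,
) -> ProfileCurve:
    """Maximize the profile likelihood L(w) and compute the 95% LRT interval.

    A coarse grid warm-starts a bounded Brent scalar optimization (local
    optima guard); the CI endpoints solve ``2 [L(w_mle) - L(w)] = 3.841``
    on each side by bisection, falling back to the search bounds (with a
    warning) when the profile is too flat to cross.
    """
    labels = np.asarray(labels, dtype=float)
    pA = np.asarray(pA, dtype=float)
    pE = np.asarray(pE, dtype=float)

    cache: dict[float, LogisticFit] = {}
    last = {"start": None}

    def fit_at(w: float) -> LogisticFit:
        key = round(float(w), 12)
        if key not in cache:
            f = profile_loglik(labels, pA, pE, w, maf_floor, start=last["start"])
            if not f.converged:  # retry from the canonical cold start
                f = profile_loglik(labels, pA, pE, w, maf_floor)
            last["start"] = (f.mu, f.gamma)
            cache[key] = f
        return cache[key]

    grid = np.linspace(bounds[0], bounds[1], n_grid)
    ll_grid = np.array([fit_at(w).loglik for w in grid])
    k = int(np.argmax(ll_grid))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda w: -fit_at(w).loglik,
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    w_mle = float(res.x)
    ll_mle = float(-res.fun)
    if ll_mle < ll_grid[k]:  # pragma: no cover - bounded Brent safeguard
        w_mle, ll_mle = float(grid[k]), float(ll_grid[k])
    fit_mle = fit_at(w_mle)

    def drop(w: float) -> float:
        return 2.0 * (ll_mle - fit_at(w).loglik) - LRT_CRIT_95

    flat = (ll_mle - ll_grid.min()) < LRT_CRIT_95 / 2.0

    def endpoint(side: float) -> float:
        a, b = w_mle, side
        if drop(b) <= 0.0:
            if flat:
                warnings.warn("flat profile likelihood: CI endpoint at search bound")
            return float(b)
        return float(optimize.brentq(drop, a, b, xtol=1e-6))

    ci = (endpoint(bounds[0]), endpoint(bounds[1]))
    return ProfileCurve(
        w_grid=grid,
        loglik_at_w=ll_grid,
        gamma_at_w=np.array([fit_at(w).gamma for w in grid]),
        mu_at_w=np.array([fit_at(w).mu for w in grid]),
        w_mle=w_mle,
        loglik_mle=ll_mle,
        ci95=ci,
        fit_mle=fit_mle,
    )


def pns_by_bins(panel: pd.DataFrame, scheme, bin_idx=None) -> pd.DataFrame:
    """Proportion of non-synonymous SNPs per bivariate MAF bin.

    The proportion is taken with respect to all SNPs in the bin (coding
    and non-coding); standard errors are binomial.  Bins with no SNPs are
    reported with missing PNS.
    """
    from .binning import assign_bins

    if bin_idx is None:
        bin_idx, _ = assign_bins(panel, scheme)
    y = panel["nonsyn"].to_numpy(dtype=float)
    rows = []
    for k in range(scheme.n_bins):
        mask = bin_idx == k
        n = int(mask.sum())
        if n == 0:
            rows.append((k, 0, np.nan, np.nan))
            continue
        pns = float(y[mask].mean())
        rows.append((k, n, pns, float(np.sqrt(pns * (1 - pns) / n))))
    out = pd.DataFrame(rows, columns=["bin", "n", "pns", "se"])
    out["afr_bin"] = out["bin"] // scheme.n_eur_bins
    out["eur_bin"] = out["bin"] % scheme.n_eur_bins
    return out


def vuong_test(per_obs_ll_a, per_obs_ll_b) -> tuple[float, float]:
    """Vuong's non-nested model comparison for equal-dimension models.

    The statistic is ``sqrt(n) * mean(d) / sd(d)`` for per-observation
    log-likelihood differences ``d``; positive favors model A.  Identical
    models give statistic 0 (p = 1) by convention; zero variance with
    unequal likelihoods is an error.
    """
    a = np.asarray(per_obs_ll_a, dtype=float)
    b = np.asarray(per_obs_ll_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("per-observation log-likelihoods must be aligned")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.allclose(a, b):
            return 0.0, 1.0
        raise ValueError("zero variance of log-likelihood differences")
    stat = float(np.sqrt(len(d)) * d.mean() / sd)
    return stat, float(2.0 * stats.norm.sf(abs(stat)))


def mcfadden_r2(fit: LogisticFit, fit_null: LogisticFit) -> float:
    """McFadden pseudo-r2 = 1 - loglik / loglik_null."""
    return 1.0 - fit.loglik / fit_null.loglik


def _fit_stats(labels, x) -> tuple[float, float]:
    fit = fit_logistic(labels, x)
    null = fit_null_logistic(labels)
    return mcfadden_r2(fit, null), fit.gamma


def jackknife_compare(
    labels_a, x_a, pos_a,
    labels_b, x_b, pos_b,
    n_blocks: int = 200,
) -> pd.DataFrame:
    """Block-jackknife comparison of two logistic fits on (possibly) different SNP sets.

    Blocks are contiguous in a shared positional coordinate (identical
    boundaries for both sets); delete-one-block re-fits give jackknife
    standard errors and normal p-values for the difference in McFadden
    pseudo-r2 and in the slope gamma.
    """
    pos_a = np.asarray(pos_a)
    pos_b = np.asarray(pos_b)
    pos_all = np.concatenate([pos_a, pos_b])
    if n_blocks > np.unique(pos_all).size:
        raise ValueError("more blocks than distinct positions")
    edges = np.quantile(pos_all, np.linspace(0, 1, n_blocks + 1))
    edges[-1] = np.inf

    full = np.array(_fit_stats(labels_a, x_a)) - np.array(_fit_stats(labels_b, x_b))
    reps = []
    for b in range(n_blocks):
        keep_a = ~((pos_a >= edges[b]) & (pos_a < edges[b + 1]))
        keep_b = ~((pos_b >= edges[b]) & (pos_b < edges[b + 1]))
        sa = np.array(_fit_stats(np.asarray(labels_a)[keep_a], np.asarray(x_a)[keep_a]))
        sb = np.array(_fit_stats(np.asarray(labels_b)[keep_b], np.asarray(x_b)[keep_b]))
        reps.append(sa - sb)
    reps = np.asarray(reps)
    se = jackknife_se(reps)
    rows = []
    for i, name in enumerate(("pseudo_r2_diff", "gamma_diff")):
        if se[i] == 0.0:
            p = 1.0 if full[i] == 0.0 else 0.0
        else:
            p = float(2.0 * stats.norm.sf(abs(full[i]) / se[i]))
        rows.append((name, full[i], se[i], p, format_pvalue(p)))
    return pd.DataFrame(rows, columns=["quantity", "estimate", "se", "p", "p_str"])


def relative_ll_gain(ll_model: float, ll_null: float, ll_reference: float) -> float:
    """Ratio of log-likelihood gains over a shared null model."""
    ref_gain = ll_reference - ll_null
    if ref_gain <= 0.0:
        raise ValueError("reference model does not improve on the null")
    return (ll_model - ll_null) / ref_gain


def standardized_gamma(
    labels, pA, pE, w_grid, maf_floor: float = 0.002
) -> pd.DataFrame:
    """Slope per w with log pmix standardized to unit variance.

    Standardizing removes the artifactual dependence of |gamma| on the
    w-varying spread of log pmix: gamma_std = gamma * sd(log pmix).
    Log-likelihoods are unchanged (affine reparameterization).
    """
    rows = []
    for w in np.asarray(w_grid, dtype=float):
        x = log_pmix(pA, pE, w, maf_floor)
        fit = fit_logistic(labels, x)
        sd = x.std()
        rows.append((w, fit.gamma, fit.gamma * sd, fit.loglik))
    return pd.DataFrame(rows, columns=["w", "gamma_raw", "gamma_std", "loglik"])
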