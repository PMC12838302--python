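"""Fixed- and random-effects meta-analysis across traits.

Inverse-variance fixed-effects combination, DerSimonian-Laird
between-trait variance (floored at zero) for the random-effects
estimate, and Cochran's Q heterogeneity test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

_Z95 = 1.959963984540054


@dataclass
class MetaResult:
    re_estimate: float
    re_se: float
    re_ci95: tuple[float, float]
    fe_estimate: float
    fe_se: float
    fe_ci95: tuple[float, float]
    tau2: float            # between-trait variance (DerSimonian-Laird)
    q_stat: float          # Cochran's Q
    q_pvalue: float
    n_traits: int


def meta_analyze(estimates, ses) -> MetaResult:
    """Random- and fixed-effects combination of per-trait estimates.

    Traits with non-finite estimates or SEs are excluded with a warning;
    at least two usable traits are required.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    ok = np.isfinite(est) & np.isfinite(se) & (se > 0)
    if not ok.all():
        warnings.warn(f"excluding {np.sum(~ok)} trait(s) with non-finite estimate/SE")
    est, se = est[ok], se[ok]
    k = est.size
    if k < 2:
        raise ValueError("meta-analysis requires at least two usable traits")

    var = se**2
    w = 1.0 / var
    fe = float(np.sum(w * est) / np.sum(w))
    fe_se = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (est - fe) ** 2))
    q_p = float(stats.chi2.sf(q, df=k - 1))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    w_re = 1.0 / (var + tau2)
    re = float(np.sum(w_re * est) / np.sum(w_re))
    re_se = float(np.sqrt(1.0 / np.sum(w_re)))
    return MetaResult(
        re_estimate=re,
        re_se=re_se,
        re_ci95=(re - _Z95 * re_se, re + _Z95 * re_se),
        fe_estimate=fe,
        fe_se=fe_se,
        fe_ci95=(fe - _Z95 * fe_se, fe + _Z95 * fe_se),
        tau2=tau2,
        q_stat=q,
        q_pvalue=q_p,
        n_traits=k,
    )
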