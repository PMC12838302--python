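"""Minor-allele-frequency transforms and bivariate MAF binning.

Everything downstream of the simulator works on folded minor allele
frequencies in two ancestries: ``pA`` (African) and ``pE`` (European).
The central quantity is the mixture frequency

    pmix = w * pA + (1 - w) * pE,

which interpolates between a European-only (w = 0) and an African-only
(w = 1) frequency model.  SNPs are stratified into bivariate (African x
European) MAF bins; bin boundaries combine fixed rare / low-frequency
cut-points with empirical quantiles of a reference MAF distribution for
the common range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: MAF boundary between "rare" and "low-frequency" variants.
RARE_MAX = 0.005
#: MAF boundary between "low-frequency" and "common" variants.
COMMON_MIN = 0.05

#: Clamp range applied to pmix before any log/power transform.  Mixture
#: weights outside [0, 1] (the optimizer searches w in [-0.5, 1.5]) can
#: push pmix outside the valid frequency range (0, 0.5].
PMIX_CLIP = (1e-6, 0.5)


def compute_pmix(pA, pE, w: float):
    """Mixture frequency ``w * pA + (1 - w) * pE``.

    Linear in ``w``; for w outside [0, 1] the result may leave (0, 0.5]
    and callers that need a valid frequency must apply :func:`clamp_pmix`.
    """
    return w * np.asarray(pA, dtype=float) + (1.0 - w) * np.asarray(pE, dtype=float)


def clamp_pmix(pmix, lo: float = PMIX_CLIP[0], hi: float = PMIX_CLIP[1]):
    """Clamp mixture frequencies into ``[lo, hi]``, logging when triggered."""
    pmix = np.asarray(pmix, dtype=float)
    n_out = int(np.sum((pmix < lo) | (pmix > hi)))
    if n_out:
        logger.debug("clamp_pmix: %d values clamped to [%g, %g]", n_out, lo, hi)
    return np.clip(pmix, lo, hi)


def floor_maf(p, floor: float):
    """Apply a lower MAF floor: ``max(p, floor)``."""
    if not (0.0 < floor < 0.5):
        raise ValueError(f"floor must lie in (0, 0.5), got {floor}")
    return np.maximum(np.asarray(p, dtype=float), floor)


@dataclass
class BinningScheme:
    """Bivariate MAF bin boundaries.

    ``afr_edges`` / ``eur_edges`` are strictly increasing boundary arrays;
    bins are left-closed / right-open except the last, which is closed at
    its upper edge (0.5 for a full scheme).  The bivariate bin index is
    ``afr_bin * n_eur + eur_bin``.
    """

    afr_edges: np.ndarray
    eur_edges: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.afr_edges = np.asarray(self.afr_edges, dtype=float)
        self.eur_edges = np.asarray(self.eur_edges, dtype=float)
        for name, e in (("afr", self.afr_edges), ("eur", self.eur_edges)):
            if e.ndim != 1 or e.size < 2:
                raise ValueError(f"{name}_edges must have at least two boundaries")
            if not np.all(np.diff(e) > 0):
                raise ValueError(f"{name}_edges must be strictly increasing")
        if not self.labels:
            self.labels = [
                f"A{i}|E{j}"
                for i in range(self.n_afr_bins)
                for j in range(self.n_eur_bins)
            ]

    @property
    def n_afr_bins(self) -> int:
        return len(self.afr_edges) - 1

    @property
    def n_eur_bins(self) -> int:
        return len(self.eur_edges) - 1

    @property
    def n_bins(self) -> int:
        return self.n_afr_bins * self.n_eur_bins


def build_univariate_edges(
    reference_mafs,
    n_common_bins: int,
    include_noncommon: bool = True,
) -> np.ndarray:
    """Univariate MAF bin edges: quantile-split common range, fixed tail bins.

    The common range [0.05, 0.5] is split at empirical quantiles (linear
    interpolation) of the reference MAFs restricted to >= 0.05.  With
    ``include_noncommon`` a low-frequency [0.005, 0.05) bin and a rare
    (0, 0.005) bin are prepended.
    """
    ref = np.asarray(reference_mafs, dtype=float)
    if ref.size == 0:
        raise ValueError("reference MAF collection is empty")
    common = ref[ref >= COMMON_MIN]
    if np.unique(common).size < n_common_bins:
        raise ValueError(
            f"reference has only {np.unique(common).size} distinct common MAF "
            f"values; cannot build {n_common_bins} common bins"
        )
    qs = np.arange(1, n_common_bins) / n_common_bins
    inner = np.quantile(common, qs, method="linear")
    edges = np.concatenate([[COMMON_MIN], inner, [0.5]])
    if include_noncommon:
        edges = np.concatenate([[0.0, RARE_MAX], edges])
    return edges


def build_binning_scheme(
    afr_reference,
    eur_reference,
    n_common_bins: int = 10,
    afr_noncommon: bool = True,
    eur_noncommon: bool = False,
) -> BinningScheme:
    """Bivariate scheme from per-ancestry reference MAF collections.

    Defaults give the estimation ("fit") layout: 12 African bins (rare,
    low-frequency, 10 common) x 10 European common bins = 120 bivariate
    bins.  ``n_common_bins=5`` with ``eur_noncommon=False`` gives the 7x5
    display layout.
    """
    if n_common_bins not in (5, 10):
        raise ValueError("n_common_bins must be 5 or 10")
    afr_edges = build_univariate_edges(afr_reference, n_common_bins, afr_noncommon)
    eur_edges = build_univariate_edges(eur_reference, n_common_bins, eur_noncommon)
    return BinningScheme(afr_edges=afr_edges, eur_edges=eur_edges)


def _digitize(p: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin index per value; -1 for values outside [edges[0], edges[-1]].

    Left-closed/right-open, last bin right-closed.
    """
    idx = np.searchsorted(edges, p, side="right") - 1
    idx[np.asarray(p) == edges[-1]] = len(edges) - 2
    out = (p < edges[0]) | (p > edges[-1])
    idx[out] = -1
    return idx


def assign_bins(
    panel: pd.DataFrame,
    scheme: BinningScheme,
    eur_common_only: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Map each SNP to a bivariate bin and summarize each bin.

    Returns ``(bin_idx, summary)`` where ``bin_idx`` holds the bivariate
    bin index per SNP (-1 = excluded) and ``summary`` has one row per
    occupied bin with columns ``bin, afr_bin, eur_bin, label, n, mean_pA,
    mean_pE``.  With ``eur_common_only`` SNPs with pE < 0.05 are excluded
    (heritability models are typically restricted to common SNPs).
    """
    pA = panel["maf_afr"].to_numpy(dtype=float)
    pE = panel["maf_eur"].to_numpy(dtype=float)
    ai = _digitize(pA, scheme.afr_edges)
    ei = _digitize(pE, scheme.eur_edges)
    excluded = (ai < 0) | (ei < 0)
    if eur_common_only:
        excluded |= pE < COMMON_MIN
    bin_idx = ai * scheme.n_eur_bins + ei
    bin_idx[excluded] = -1

    keep = bin_idx >= 0
    df = pd.DataFrame({"bin": bin_idx[keep], "pA": pA[keep], "pE": pE[keep]})
    grouped = df.groupby("bin")
    summary = pd.DataFrame(
        {
            "n": grouped.size(),
            "mean_pA": grouped["pA"].mean(),
            "mean_pE": grouped["pE"].mean(),
        }
    ).reset_index()
    summary["afr_bin"] = summary["bin"] // scheme.n_eur_bins
    summary["eur_bin"] = summary["bin"] % scheme.n_eur_bins
    summary["label"] = [scheme.labels[k] for k in summary["bin"]]
    summary = summary[["bin", "afr_bin", "eur_bin", "label", "n", "mean_pA", "mean_pE"]]
    return bin_idx, summary
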