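"""Shared fixtures: small seeded synthetic panels and binning objects."""

import numpy as np
import pandas as pd
import pytest

import alphamix as am


@pytest.fixture(scope="session")
def small_panel() -> pd.DataFrame:
    """8k-SNP panel with correlated African/European folded MAFs."""
    return am.simulate_maf_panel(8_000, seed=11)


@pytest.fixture(scope="session")
def common_panel() -> pd.DataFrame:
    """20k-SNP panel conditioned on European MAF >= 0.05."""
    return am.simulate_common_panel(20_000, seed=13)


@pytest.fixture(scope="session")
def fit_scheme(common_panel):
    """12 African x 10 European bivariate binning scheme."""
    return am.build_binning_scheme(
        common_panel["maf_afr"], common_panel["maf_eur"], n_common_bins=10
    )


@pytest.fixture(scope="session")
def common_bins(common_panel, fit_scheme):
    bin_idx, summary = am.assign_bins(common_panel, fit_scheme, eur_common_only=True)
    return bin_idx, summary


def make_noiseless_table(summary, w, alpha, sigma2, trait="t"):
    """Bin-variance table generated exactly from the mixture variance model."""
    tab = summary[["bin", "n", "mean_pA", "mean_pE"]].copy()
    tab.insert(0, "trait", trait)
    tab["beta2_hat"] = am.predict_bin_variance(
        w, alpha, sigma2, tab["mean_pA"], tab["mean_pE"]
    )
    return tab


@pytest.fixture(scope="session")
def noiseless_table(common_bins):
    _, summary = common_bins
    return make_noiseless_table(summary, w=0.8, alpha=-0.5, sigma2=3.0)
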