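"""Readers and writers for the pipeline's plain-text exchange formats.

* SNP panels: tab-separated with a fixed header.
* Summary statistics: the LDSC sumstats dialect (SNP, A1, A2, N, Z).
* Bin-variance tables: tab-separated (trait, bin, n, mean_pA, mean_pE,
  beta2_hat) — the exchange format with externally computed stratified
  LD-score regression output.
* Binning schemes: YAML (edges + labels), so jackknife replicates and
  separate runs reuse identical boundaries.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binning import BinningScheme

PANEL_COLUMNS = [
    "snp_id",
    "pos_index",
    "freq_afr",
    "freq_eur",
    "maf_afr",
    "maf_eur",
    "nonsyn",
    "beta",
]


def write_panel(panel: pd.DataFrame, path) -> None:
    out = panel.copy()
    for col in PANEL_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out[PANEL_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_panel(path) -> pd.DataFrame:
    """Read a panel, enforcing the folded-MAF invariants.

    Malformed frequencies are reported with the offending line number
    (header = line 1).
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(PANEL_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ValueError(f"panel file {path} is missing columns {sorted(missing)}")
    for col in ("freq_afr", "freq_eur", "maf_afr", "maf_eur"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if col.startswith("maf"):
            bad |= (vals <= 0) | (vals > 0.5)
        else:
            bad |= (vals <= 0) | (vals >= 1)
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2
            raise ValueError(f"{path}: invalid {col} at line {line}")
        df[col] = vals
    if df["nonsyn"].isna().all():
        df = df.drop(columns=["nonsyn"])
    else:
        df["nonsyn"] = df["nonsyn"].astype(int)
    if df["beta"].isna().all():
        df = df.drop(columns=["beta"])
    return df


def write_sumstats(sumstats: pd.DataFrame, path) -> None:
    """LDSC sumstats dialect; alleles are placeholders (folded frequencies)."""
    out = pd.DataFrame(
        {
            "SNP": sumstats["snp_id"],
            "A1": "A",
            "A2": "G",
            "N": sumstats["n"],
            "Z": sumstats["z"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = {"SNP", "N", "Z"} - set(df.columns)
    if missing:
        raise ValueError(f"sumstats file {path} is missing columns {sorted(missing)}")
    return pd.DataFrame(
        {"snp_id": df["SNP"], "z": df["Z"], "n": df["N"], "chi2": df["Z"] ** 2}
    )


def write_bin_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_bin_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = {"trait", "bin", "n", "mean_pA", "mean_pE", "beta2_hat"} - set(df.columns)
    if missing:
        raise ValueError(f"bin table {path} is missing columns {sorted(missing)}")
    return df


def write_annot(annot: np.ndarray, snp_ids, path, names=None) -> None:
    """LDSC annot-style indicator matrix: one column per bivariate bin."""
    names = names or [f"bin_{d}" for d in range(annot.shape[1])]
    df = pd.DataFrame(annot.astype(int), columns=names)
    df.insert(0, "SNP", np.asarray(snp_ids))
    df.to_csv(path, sep="\t", index=False)


def write_scheme(scheme: BinningScheme, path) -> None:
    payload = {
        "afr_edges": [float(x) for x in scheme.afr_edges],
        "eur_edges": [float(x) for x in scheme.eur_edges],
        "labels": list(scheme.labels),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_scheme(path) -> BinningScheme:
    payload = yaml.safe_load(Path(path).read_text())
    return BinningScheme(
        afr_edges=np.asarray(payload["afr_edges"], dtype=float),
        eur_edges=np.asarray(payload["eur_edges"], dtype=float),
        labels=list(payload.get("labels") or []),
    )
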