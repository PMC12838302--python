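"""Simulate the synthetic study data: MAF panel, labels, effects, GWAS z-scores.

Draws a common-SNP panel with correlated African/European folded MAFs
and a bottleneck-distorted European spectrum, labels SNPs as
non-synonymous under the logistic mixture model, assigns sparse causal
effects under the MAF-mixture variance law, and writes one trait's
summary statistics.  Artifacts go to results/panel/.
"""

from pathlib import Path

import numpy as np

import alphamix as am
from alphamix import io

OUT = Path(__file__).resolve().parent.parent / "results" / "panel"
OUT.mkdir(parents=True, exist_ok=True)

cfg = am.GenerativeConfig(seed=1)
panel = am.simulate_common_panel(cfg.n_snps, cfg.drift_afr, cfg.drift_eur, seed=cfg.seed)
panel = am.label_nonsynonymous(panel, w=cfg.w_true, seed=cfg.seed + 1)
panel = am.simulate_causal_effects(panel, cfg, seed=cfg.seed + 2)
ss = am.simulate_sumstats_direct(panel, cfg.gwas_n, seed=cfg.seed + 3)

io.write_panel(panel, OUT / "panel.tsv")
io.write_sumstats(ss, OUT / "sumstats_trait0.tsv")

r = np.corrcoef(panel["maf_afr"], panel["maf_eur"])[0, 1]
print(f"panel: {len(panel)} SNPs with European MAF >= 0.05")
print(f"  corr(pA, pE) = {r:.3f}")
print(f"  African rare (<0.005): {(panel.maf_afr < 0.005).mean():.3%}, "
      f"low-frequency: {((panel.maf_afr >= 0.005) & (panel.maf_afr < 0.05)).mean():.3%}")
print(f"  non-synonymous fraction: {panel.nonsyn.mean():.3%}")
p = panel["freq_eur"].to_numpy()
gvar = np.sum(2 * p * (1 - p) * panel["beta"].to_numpy() ** 2)
print(f"  causal SNPs: {(panel.beta != 0).sum()}, genetic variance = {gvar:.3f} (h2 target {cfg.h2})")
print(f"  mean chi2 = {ss.chi2.mean():.3f} at N = {cfg.gwas_n}")
print(f"wrote {OUT}/panel.tsv and sumstats_trait0.tsv")
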