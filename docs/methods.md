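# Methods

## The model

Per-allele effect-size variance of a SNP is modeled as a function of a
mixture of its folded minor allele frequency (MAF) in two ancestries —
African (`pA`, not distorted by the out-of-Africa bottleneck) and
European (`pE`, the GWAS population):

    E[beta_t^2 | pA, pE] = (sigma_{g,t}^2 / 2) * [pmix (1 - pmix)]^alpha,
    pmix = w * pA + (1 - w) * pE.

`w` is the mixture weight (0 = European-only, the standard single-
population alpha model; 1 = African-only), `alpha` < 0 encodes the
strength of the MAF dependence induced by negative selection, and
`sigma_{g,t}^2` is a per-trait scale.  A companion logistic model treats
non-synonymous status, a proxy for selection strength, the same way:

    logit P(nonsyn) = mu + gamma * log(pmix),

with MAFs floored at 0.002 before mixing.

## Estimation

**Bin-wise variance moments.**  SNPs with `pE >= 0.05` are stratified
into 120 bivariate MAF bins (12 African: rare < 0.005, low-frequency
[0.005, 0.05), 10 common quantile bins; by 10 European common quantile
bins; boundaries are empirical quantiles with linear interpolation,
left-closed/right-open, last bin closed at 0.5).  The mean per-allele
effect variance of each bin and trait is estimated by a stratified
LD-score regression of GWAS chi-square statistics on per-annotation LD
scores, `E[chi2_i] = 1 + N * sum_d tau_d l_{i,d}`.  The synthetic data
contain no LD, so the LD score of a bin annotation is its indicator,
heteroskedasticity weights are near-constant (unweighted OLS is used),
and — because the bin indicators partition the panel — the intercept is
fixed at its exact null value 1 (a free intercept would be exactly
collinear; the function supports both conventions).  Per-SNP
heritability `h2_i = sum_d a_d(i) tau_d` is converted to per-allele
variance via the Hardy-Weinberg genotype variance,
`beta2_i = h2_i / (2 pE_i (1 - pE_i))`; negative estimates are retained,
never truncated.

**GMM fit.**  (w, alpha) minimize the SNP-count-weighted squared
deviation between the model prediction at the bin-mean MAFs and the
bin-wise estimates, summed over bins and traits.  For fixed (w, alpha)
the per-trait scale has the closed form
`sigma^2 = 2 sum_k n_k b_k g_k / sum_k n_k g_k^2` with
`g_k = [pmix_k (1 - pmix_k)]^alpha`, so the numerical search is
2-dimensional: differential evolution (population 30, up to 200
generations, seeded, followed by an L-BFGS-B polish) over
`w in [-0.5, 1.5]`, `alpha in [-1.5, 1.5]`.  Mixture frequencies are
clamped to `[1e-6, 0.5]` before exponentiation (weights outside [0, 1]
can push pmix out of the frequency range); clamping events are logged.
Two moment forms are supported: transforming the bin-mean pmix
(default), or averaging the per-SNP transform within each bin,
optionally thresholding per-SNP pmix at a plateau value T.  A coarse
grid scan flags non-identifiability (distant parameter points with
numerically equal loss); the reported optimum is then the candidate with
smallest |w - 0.5|.

**Profile likelihood for the logistic model.**  For each w the nuisance
parameters (mu, gamma) are maximized out by a two-parameter IRLS/Newton
fit with step-halving line search (monotone ascent; relative gradient
tolerance 1e-8 per observation, ridge 1e-10 on the information matrix,
separation detected and raised).  L(w) is maximized by a 31-point grid
warm-starting bounded Brent minimization on [-0.5, 1.5]; 95% CIs solve
`2 [L(w_hat) - L(w)] = 3.841` by bisection, and p-values against fixed
w use the 1-df likelihood-ratio test, floored in reports at 1e-15.
Natural logs are used throughout (the base only rescales gamma).

**Uncertainty.**  Genomic block jackknife: contiguous positional blocks
with counts differing by at most one (default 200), identical boundaries
across traits; `SE^2 = (B-1)/B * sum_b (theta_(b) - theta_bar)^2`, CIs
are +-1.96 SE, p-values two-sided normal.  Cross-trait combination uses
inverse-variance fixed effects and DerSimonian-Laird random effects with
the between-trait variance floored at zero (statsmodels'
`combine_effects` does not floor it and divides by zero on homogeneous
inputs, so the estimator is computed explicitly; statsmodels is the
cross-check in tests).  Trait selection for multi-trait analyses is
greedy: filter to heritability z > 6 and N*h2 > 20,000, then accept in
descending N*h2 order subject to squared genetic correlation < 0.1 with
every already-selected trait.

## The synthetic-data generator

The generator emulates the joint statistical structure the estimator
consumes, not the underlying population genetics:

* Ancestral frequencies `q0` follow a 1/q density truncated to
  [5e-4, 1 - 5e-4] (the neutral SFS shape); present-day frequencies are
  Balding-Nichols Beta draws around `q0` with drift `F_afr = 0.01`,
  `F_eur = 0.12`, then clipped to [1e-6, 1 - 1e-6] and folded.  These
  drifts are emulation knobs, not demographic claims: they give
  corr(pA, pE) near 0.8 genome-wide and an excess of European-rare
  variants (the bottleneck signature).
* Non-synonymous labels are Bernoulli under the logistic model.  The
  realistic slope is weak (fitted slopes in large cohorts are about
  -0.1 to -0.17); defaults gamma = -0.13, mu = -5 give a label rate
  near 1%.
* `n_causal` SNPs drawn uniformly receive
  `beta ~ Normal(0, [q(1-q)]^alpha)` with `q = max(T, pmix)` — the
  plateau threshold `T = 0.005` caps per-allele variance growth at low
  MAF, deliberately absent from the inference model.  The
  proportionality constant is irrelevant: all effects are rescaled by
  one constant so the genetic variance `sum 2 p (1-p) beta^2` equals
  `h2 = 0.5` exactly (phenotypic variance 1).
* Z-scores come either from the unlinked non-centrality
  (`z = sqrt(N) beta sqrt(2p(1-p)) + e`, `e ~ N(0,1)`) or from an
  explicit `Y = X beta + eps` genotype simulation (validation mode,
  size-capped); the two agree in per-bin mean chi-square within Monte
  Carlo error.

What the generator does **not** emulate: linkage disequilibrium (bin
moments are estimated from independent SNPs, so LD-induced correlation
of moment errors across bins is absent), functional annotation
structure, case/control traits, and non-infinitesimal effect-size
mixtures beyond sparsity.  Passing tests therefore validate the
estimation machinery and its sampling behavior under independent noise;
they do not certify behavior under real LD (see Limitations).

## Desk-scale study conditions

The reference simulation design is a biobank-scale GWAS: M = 5,907,305
SNPs with `pE >= 0.05`, N = 337,448, 10,000 causal SNPs, h2 = 0.5,
alpha = -0.38, T = 0.005, joint fits across 25 traits.  The package's
study runs at M = 50,000.  Scaling N proportionally would preserve
per-SNP non-centrality but inflate the per-bin relative standard error
of the variance moments by sqrt(M_full/M) (about 11x) and starve bins of
causal SNPs — a different operating regime.  Instead the desk-scale
design preserves the estimator's noise regime:

* `N = N_full * sqrt(M/M_full) = 31,047` keeps the chi-square-noise
  component of the per-bin relative SE,
  `SE(tau_k)/tau ~ M sqrt(2/n_k) / (N h2)`, at its full-scale value;
* `n_causal = 10,000` (unchanged) keeps the per-bin causal count
  (~83), the other dominant noise source, at its full-scale value.

Both matches follow from closed-form binomial/chi-square theory.  The
same information-preservation logic governs the profile-likelihood
recovery experiments: at n = 1e5 panel SNPs the realistic slope
gamma = -0.13 leaves w barely identified (the reference data had ~3e7
SNPs), so recovery and coverage experiments use gamma = -1.0 with
mu = -8.0 (label rate ~5%, no saturation), which restores per-replicate
precision comparable to the full-size analysis.

## Numerical choices and degenerate inputs

* Folding guard: simulated frequencies clipped to [1e-6, 1 - 1e-6].
* Empty bivariate bins are dropped from tables (and from the annotation
  design, where an all-zero column would be collinear).
* Oracle causal-only bins without causal SNPs are excluded.
* A constant logistic predictor, single label class, or complete
  separation raise immediately rather than returning garbage.
* Flat profile likelihoods return the search-bound CI with a warning.
* Ties among GMM optima are broken toward |w - 0.5| and flagged.

## Limitations

* No LD: the full-scale estimator's upward bias of w at generative
  w = 0 (driven by LD-structured moment noise in stratified LD-score
  regression) does not reproduce under independent noise; the
  desk-scale estimator is unbiased there.  The attenuation of w at high
  truth values and the downward alpha bias near w = 0.95 do reproduce.
* The stratified regression stage is a simplified unlinked analogue of
  S-LDSC (no reference-panel LD scores, no baseline annotations, no
  regression-SNP filtering); its exact weighting/intercept conventions
  in production pipelines are not replicated.
* Two ancestries only; no allele-age information; no coalescent or
  forward simulation.
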