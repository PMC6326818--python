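# Methods

## Problem and model

Epigenetic field defects are early DNA methylation alterations present in
histologically normal tissue adjacent to a tumor. At the CpG level they are
typically weak, and they are often driven by a handful of outlier samples —
a variance signal rather than a mean signal. Site-level EWAS tests pay a
multiplicity penalty proportional to the number of CpGs in a gene and miss
such weak, dense signals. `epifield` implements a gene-level alternative: a
weighted epigenetic distance between samples that accumulates both mean
(DM) and variance (DV) signals across the CpGs of a gene, tested for
association with case/control status by distance-based regression and
calibrated by permutation.

For one gene with *n* CpGs and 2*N* samples:

1. **Features.** X^m (2N × n) holds the beta values. X^v holds
   *variability scores* x^v_ij = (x^m_ij − x̄^m_j)², where x̄^m_j is the
   mean of CpG *j* within sample *i*'s own group, so that a group
   difference in variance becomes a group difference in the mean of X^v.
   The concatenation X^mv = [X^m, X^v] is column-standardized (mean 0,
   SD 1, denominator 2N − 1); exactly constant columns map to zero.
2. **Weights.** Per CpG, a two-sided pooled-variance t-test gives p^m_j and
   a one-sided two-group Levene test (t-test on absolute deviations from
   the group mean, alternative "cases more variable") gives p^v_j. Weights
   are w_j = −log10(p_j) / Σ_j −log10(p_j), separately per signal type, so
   Σ w^m = Σ w^v = 1. If every p of a type equals 1 the weights fall back
   to 1/n; p-values are floored at 1e−300 before the logarithm.
3. **Distance.** d²_st = Σ_j c^m_j (x^m_sj − x^m_tj)² + c^v_j (x^v_sj −
   x^v_tj)², with coefficients (w^m_j/2, w^v_j/2) for the weighted DM-DV
   variant, (1/2n, 1/2n) unweighted, and single-block variants (DM, DV,
   weighted or not) renormalized so coefficients sum to one. The
   renormalization constant of the single-block variants is a free choice:
   the pseudo-F is invariant to any positive rescaling of the distance, so
   it only fixes a display scale.
4. **Pseudo-F.** With A = (−d²_st/2), G = CAC (Gower centering,
   C = I − 11ᵀ/2N) and H the projection onto the raw 0/1 label vector,
   F = tr(HGH) / tr[(I−H)G(I−H)]. Because H is idempotent both traces
   reduce to closed forms in y: tr(HGH) = yᵀGy/(yᵀy) and the denominator
   is tr(G) minus the same quantity. H deliberately has no intercept
   column; since G is double-centered the quadratic form equals the
   centered one and only the yᵀy scaling differs from the classical
   PERMANOVA convention, which is available as
   `f_convention="permanova"` for comparison. With groups of fixed size
   and normalized coefficients the two conventions give identical
   permutation p-values. A nonpositive denominator (no dispersion) flags
   the statistic undefined; such genes are treated as non-significant.
5. **Inference.** Each permutation shuffles the labels globally — once per
   permutation, shared by all genes — and repeats steps 1–4, including the
   recomputation of variability scores, standardization of X^v, site
   p-values and weights (X^m and its standardization are label-free).
   Empirical p-values pool the permuted statistics of all G genes:
   p_g = Σ_g′ {1 + Σ_perm 1(F_{g′,perm} ≥ F_g)} / (G (n_perm + 1)),
   granularity 1/(G (n_perm+1)), minimum attainable value 1/(n_perm+1).
   Ties count against significance. An alternative reading that pools the
   observed statistics instead of adding 1 per gene is available as
   `pooling="pooled-observed"`; the default follows the formula above.

### EWAS baselines

`EWAS-DM`/`EWAS-DV` run the same site tests per CpG and Bonferroni-adjust
within the gene: the gene is significant when min_j min(1, n·p_j) passes
the threshold. `EWAS min-P` takes the minimum adjusted p over both signal
types of all CpGs (capped at 1 — the cap is ours; an uncapped product is
not a p-value) and reports which CpG and which test achieved it.

## Numerical and implementation choices

- **Two engines.** The reference engine walks the module pipeline
  (features → weights → distances → Gower → pseudo-F) per permutation. The
  production engine evaluates all label configurations at once in rescaled
  feature space, using that for Euclidean distances tr(G) = ‖Z_c‖²_F and
  yᵀGy = ‖Z_cᵀy‖² for the column-centered embedding Z_c; this is O(N n)
  per configuration instead of O(N²). The two are tested to agree to
  1e−10 on every variant; distance matrices themselves are computed in
  pairwise-difference form, never via a Gram-matrix shortcut that can put
  small negatives under the square root.
- **Degenerate site tests.** Zero pooled variance with equal means gives
  p = 1 (no evidence); with unequal means the p-value floor. Constant
  feature columns are detected by exact max = min (robust to rounding in
  the mean of identical floats) and standardized to zero with a warning.
- **Missing data.** Coverage filters run samples-first (default: ≥95% CpG
  coverage per sample, then ≥70% sample coverage per CpG). Entries still
  missing afterwards are imputed per CpG with the group-specific mean
  (configurable to `error`); the feature equations are undefined under
  missingness and complete data are untouched by this rule.
- **Canonical order.** Samples are internally reordered controls-first;
  the permutation stream is drawn after reordering, so results are a pure
  function of (data, labels, seed). No parallelism is used, which keeps
  determinism trivial.
- **t-test flavor.** Pooled-variance Student by default (groups are
  equal-sized in the study design this targets); Welch behind a flag.
  Levene center is the group mean (classic), median (Brown–Forsythe)
  behind a flag. The one-sided Levene is realized as the one-sided t on
  absolute deviations — the unique directional two-group version; the
  F-form is unsigned.

## Synthetic data

The generator emulates case-control 450K beta values. Noise CpGs are
Beta(a₀ = 46.36, b₀ = 52.28) in both groups — mean 0.47, SD 0.05, the
average moments of normal-tissue CpGs the design targets — with 40 cases
and 40 controls by default. Effects are realized by method-of-moments
re-solving of the shape parameters: a mean signal adds `mean_diff`
(grid 0.02–0.1) at fixed SD; a variance signal multiplies the SD by
`sd_ratio` (grid 1.25–2.5) at fixed mean. Field-defect scenarios draw each
case at each signal CpG from a Bernoulli(p) mixture (p ∈ {0.10, 0.15,
0.20}): outliers come from a beta with mean shifted by +0.2 at baseline SD
(the shift is a knob; the reference magnitude is not published, and +0.2 =
4 baseline SDs makes an unmistakable outlier without leaving (0, 1)).
Optional AR(1) dependence (ρ = 0.5 by default) among a gene's CpGs is
induced by a Gaussian copula — AR(1) recursion on a latent normal vector,
mapped through Φ and the inverse beta CDF — which preserves every CpG's
beta marginal exactly.

What the generator does *not* emulate: array normalization artifacts,
batch effects, cell-type composition, probe cross-reactivity, spatially
varying baseline means across CpGs, and covariates. Passing tests
therefore demonstrate calibration and relative power under the idealized
beta model, not performance on raw array data.

## Experiment scales

Monte-Carlo experiments default to 200 simulations with 199 permutations
(the full-scale protocol of 1000 × 999 is a parameter change away). All
methods are evaluated on the same simulated datasets, and the distance
variants share label shuffles within each dataset, so method contrasts
are paired. One exception: the 10-gene familywise cells Bonferroni-adjust
the pooled p-values to 0.05/10 = 0.005, and with 199 permutations the
smallest attainable pooled p-value is exactly 1/200 = 0.005 — the call
would degenerate to "observed maximum beats every permuted value". Those
cells therefore use 999 permutations, which makes p ≤ 0.005 reachable
with up to 40 pooled exceedances. Type-I error is the proportion of
simulations with any significant gene (Bonferroni-adjusted when G > 1);
power is the same proportion under a signal scenario.

## Known limitations

- Continuous phenotypes and covariate adjustment are out of scope; the
  projection H is built from the binary label only.
- Permutation cost grows linearly in genes × permutations ×
  simulations; genome-wide runs (~19k genes) are feasible but should
  raise `n_perm` for resolution (the pooled formula already shares the
  pool across genes to that end).
- The variability-score centering follows the within-group reading
  (means taken over cases and controls separately); this is what makes
  X^v carry differential variability, and the permutation null is
  recomputed consistently under the same rule.
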