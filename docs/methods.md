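# Methods

## Model

`prsbilevel` estimates polygenic-score weights from GWAS summary statistics
under a Bayesian linear model on standardized genotypes `G` (N × M) and a
standardized phenotype `y`:

    y | G, beta, sigma^2      ~  MVN(G beta, sigma^2 I_N)
    beta_j | sigma^2, scales  ~  N(0, (sigma^2 / N) * delta^2_{A(j)} * lambda^2_j)
    delta_k  ~ C+(0, 1)   (one per annotation group k = 1..K)
    lambda_j ~ C+(0, 1)   (one per variant copy)
    p(sigma^2) ∝ 1 / sigma^2

This is a bilevel global–local (horseshoe-type) shrinkage prior: the local
half-Cauchy scale `lambda_j` adapts to individual variants, while the group
scale `delta_k` lets whole annotation categories (gene-based classes,
pathways) be shrunk more or less than others. With K = 1 the model collapses
to the fully Bayesian single-global-scale continuous-shrinkage PRS
(the PRS-CS-auto special case of the gamma–gamma family at a0 = 0.5,
b0 = 1), which the package exposes as `PRSCSAuto`.

Individual-level data never enter the fit. With `beta_hat = G^T y / N`
(marginal GWAS effects on the standardized scale) and `D = G^T G / N`
(LD from an external reference panel, block-diagonal by assumption), the
full conditionals are

    beta_b | .    ~  MVN( (D_b + Psi_b^{-1})^{-1} beta_hat_b,
                          (sigma^2/N) (D_b + Psi_b^{-1})^{-1} )   per block b
    sigma^2 | .   ~  IG( (N + M')/2,
                         N/2 [1 - 2 beta' beta_hat + beta'(D + Psi^{-1}) beta] )

with `Psi = diag(delta^2_{A(j)} lambda^2_j)` and M' the number of
(variant, group) copies. Each half-Cauchy scale is decomposed as a scale
mixture of inverse gammas (`x^2 | a ~ IG(1/2, 1/a)`, `a ~ IG(1/2, 1)`),
giving conjugate updates with auxiliaries `t_k` and `c_j`:

    delta^2_k | .  ~ IG( (M_k + 1)/2,
                         sum_{j in k} N beta_j^2 / (2 sigma^2 lambda_j^2) + 1/t_k )
    t_k | .        ~ IG( 1, delta_k^{-2} + 1 )
    lambda^2_j | . ~ IG( 1, N beta_j^2 / (2 sigma^2 delta^2_{A(j)}) + 1/c_j )
    c_j | .        ~ IG( 1, lambda_j^{-2} + 1 )

These are the `lambda_conditional="derived"` forms (the default). The
package also retains an `"as_printed"` mode whose delta^2/lambda^2 rates use
the auxiliary variables directly (`+ t_k`, `+ c_j`) and omit `delta^2` from
the lambda^2 rate; that variant has no consistent joint density — iterating
its prior cycle does not preserve the half-Cauchy marginal, and its chain
does not match deterministic grid integration of the model — so only
`"derived"` is claimed correct. Both modes are exercised by tests.

### Overlapping annotations

A variant in several groups is expanded into one copy per group. Copies
share the variant's row/column of D (a duplicated design column) and its
beta_hat entry; each copy has its own `lambda^2` and its group's `delta^2`;
the variant's total effect is the sum of its copies' posterior means.
Multi-annotated variants therefore receive systematically less shrinkage —
the intended prioritization of variants with more annotations.

### Interweaving step

The likelihood constrains only the products `psi_j = delta^2 lambda^2_j`,
so the split between the group and local scales is weakly identified and
mixes poorly under the plain scan. After the standard updates, the sampler
resamples each `delta^2_k` from its exact conditional *given the products*
(a generalized inverse Gaussian), then rescales the `lambda^2_j`
accordingly. This reparametrized Gibbs step leaves the posterior unchanged
(the 1- and 2-SNP chains still match grid integration to < 0.01) while
making the reported per-group `delta^2` posterior means meaningful in
finite chains; without it the delta/lambda split drifts along its
non-identified direction and per-group averages are dominated by heavy-tail
excursions.

### Numerical guards

- The per-copy product `delta^2 lambda^2` is clipped above at `shrink_cap`
  (default 1.0, i.e. prior variance at most `sigma^2/N`) before the beta
  update, and the stored `lambda^2` is truncated to match, following the
  convention of summary-statistic continuous-shrinkage samplers. Oracle
  tests disable the cap.
- The nominal sigma^2 rate can go negative when M' > N (the
  summary-statistic residual overfits); it is floored at the prior
  quadratic term `N/2 sum beta_j^2/psi_j`. Without this floor sigma^2
  collapses and the scale updates diverge.
- Near-singular LD blocks can optionally be ridge-repaired
  (`(D + eps I)/(1 + eps)`, eps = 1e-6) behind an explicit flag, off by
  default.

### Chain settings

Defaults: 1000 iterations, 500 burn-in, thinning 5 (100 kept draws), one
seeded generator, fixed update order. The 1-/2-SNP oracle tests validate
that these lengths are adequate for posterior means at the problem sizes
used here; the `GibbsConfig` dataclass exposes all of them.

## Scoring and combination weights

Group-wise scores are `PRS_k = sum_{j in k} G_j beta_tilde_{j,k}` on
standardized genotypes. The final score is `sum_k alpha_k PRS_k`; `alpha`
is estimated by 10-fold cross-validation on a separate individual-level
validation set — per fold, ordinary least squares (quantitative traits) or
unpenalized logistic regression (binary traits, folds stratified by case
status) of the phenotype on the K score columns plus an intercept; held-out
folds provide AUC / R^2 / Efron pseudo-R^2; the exported `alpha` is the
across-fold mean. The regression family and the averaging rule are design
choices (the CV protocol fixes only the 9/10-train, 1/10-validate split);
a non-negativity constraint on alpha is available behind a flag. The hybrid
score adds an externally supplied conventional PRS as one more regression
column, so its weight `gamma` is fitted jointly with alpha.

## Comparators

- `PRSCSAuto`: the K = 1 special case, run through the identical code path
  (bitwise-reproducible against a K = 1 bilevel run at equal seed).
- `LDpredFunct`: closed-form posterior mean `E[beta|.] = W^{-1} N beta_hat`
  with `W = N D + (1/c) diag(1/sigma_j^2)` per block, where `sigma_j^2` are
  externally supplied per-SNP heritabilities and the normalizing constant c
  is chosen so `sum_j c sigma_j^2` equals the trait heritability (the
  constant's definition is otherwise unspecified; this is our convention).
  Zero-heritability variants get zero effect. SNPs are ranked by |posterior
  mean| and partitioned into L = 40 bins of approximately equal sum of
  squared effects by a greedy pass whose per-bin target is re-computed from
  the remaining mass (deterministic; guarantees every bin is used); the bin
  scores feed the same cross-validated weighting as annotation groups. In
  simulations the true per-SNP heritabilities are supplied; estimating them
  by stratified LD-score regression is out of scope.

## Synthetic data

The simulator reproduces the simulation design end-to-end at a configurable
scale. Full-scale presets: M = 125,000 SNPs in K annotation groups with the
tabulated sizes, causal percentages p_k and heritability shares q_k;
N_sumstat = 50,000; N_test = 24,000; h^2 = 0.7. Seven settings cover sparse
(0, 0, 10, 90), intermediate, balanced (25 × 4), many-group (K = 10) and
two overlapping configurations.

- **Genotypes.** Per block, two latent AR(1) Gaussian haplotypes
  (correlation rho^|i-j|, rho = 0.7) thresholded at a MAF drawn uniformly
  from (0.01, 0.5) give 0/1/2 dosages, then column-standardized. The D
  handed to the samplers comes from an independent 500-individual reference
  draw of the same process, mirroring an external LD panel. This stand-in
  reproduces blockwise LD and allele-frequency variation but not real
  haplotype structure, long-range LD, or relatedness.
- **Effects.** Point-normal per variant: causal with probability p_{A(j)},
  effect `N(0, q_{A(j)} h^2 / (p_{A(j)} M))`. As printed, this variance
  makes group k's expected heritability contribution proportional to
  `q_k M_k / M` rather than q_k alone; a `variance_mode="group_normalized"`
  flag substitutes M_k for M. The default implements the printed formula.
  For multi-annotated variants the generating group is the member group
  with the largest q_k (the generative rule for such variants is otherwise
  unspecified). Groups with q_k = 0 contribute no causal effects.
- **Phenotypes.** `y = G beta + eps` with the noise drawn orthogonal to
  `G beta` in-sample and scaled so the realized genetic-variance fraction
  equals h^2 exactly; y is standardized.
- **GWAS.** Marginal effects `beta_hat = G^T y / N` on standardized data.
  (The original pipeline used a mixed-model association test; for unrelated
  simulated individuals with Gaussian phenotypes the marginal estimate
  coincides, so the simulator regresses directly.)
- **Scaling.** `scale` shrinks M and both N proportionally
  (largest-remainder rounding keeps group sizes exact: scale 0.02 gives
  M = 2,500 = 995 + 750 + 503 + 252, N_sumstat = 1,000, N_test = 480). The
  LD block size scales with the genome (500 × scale, floor 25 SNPs),
  treating the reduced genome as proportionally thinned.
- **Overlap geometry.** The exact overlap layout of the original study is
  not recoverable; patterns are parameterized by a target IOU (default
  0.5) placed between the two zero-heritability groups (pattern I) or the
  two heritable groups (pattern II), with group sizes taken from the design
  table and shared variants counted once. At IOU 0.5 with these size
  ratios, pattern II makes the 90%-heritability group essentially a subset
  of the 10% group — an unavoidable consequence of the published group
  sizes, worth keeping in mind when reading the pattern contrast below.

## Evaluation

AUC uses Mann–Whitney U with half-weight ties; for simulated quantitative
phenotypes, cases are the top decile of the phenotype itself (ceil(n/10)
cases, stable tie-break by index); threshold labellers (e.g. BMI 25 kg/m^2,
LDL 4.1 mmol/L) are provided for real-data use. R^2 is the squared Pearson
correlation; Efron's pseudo-R^2 `1 - sum(y - p)^2 / sum(y - ybar)^2` serves
binary traits.

## What the desk-scale experiments do and do not show

The packaged experiments run at scale 0.02 (M = 2,500, N_sumstat = 1,000,
N_test = 480, 10 replicates), sizes chosen so the full comparison suite
completes on a single CPU in minutes. At this scale:

- The sparse setting (0, 0, 10, 90) shows a large, consistent AUC advantage
  of the bilevel model over the single-group model (every replicate in our
  runs; paired one-sided p < 0.001), the qualitative analogue of the
  full-scale result.
- Per-group `delta^2` posterior means rank the 90%-heritability group above
  both zero-heritability groups in roughly 7 of 10 replicates, not
  near-deterministically. The expected causal count in that group is only
  ~5 (Binomial(252, 0.02)), so the realized architecture often departs
  far from its nominal sparsity; group-scale recovery is data-limited at
  this size, not sampler-limited (longer chains do not change the
  ranking, and the conditionals match the integration oracle).
- In the balanced setting the two methods differ by ~0.01 AUC rather than
  ~0: with so few causal variants per group the realized heritability
  shares fluctuate around equality, and the group-wise weighting exploits
  that fluctuation; the full-scale near-equivalence emerges only as M_k
  grows.
- In the overlap contrast, the copy-expansion boost to multi-annotated
  variants dominates at desk scale: pattern II doubles exactly the causal
  variants (see the nesting note above) and often gains *more* than
  pattern I, the reverse of the full-scale ordering, where the
  group-scale-correlation mechanism dominates instead.

None of these desk-scale results quantify performance on real cohorts; the
generator omits real LD structure, case-control ascertainment and
covariates, and the full-scale study conditions (125,000 SNPs, N = 50,000)
are out of reach of this test harness by design.

## Known limitations

- Cross-block LD is assumed zero; block boundaries are taken as given.
- A single GWAS N is used for all variants (a per-variant N column is
  accepted with the median used and a warning).
- alpha regression carries no covariates (age, sex, principal components).
- The `as_printed` conditional mode is retained for comparison only.
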