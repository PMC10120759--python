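# prsbilevel

Polygenic risk scores (PRS) summarize an individual's genetic liability as a
weighted sum of allele dosages. The weights are usually posterior effect
sizes inferred from GWAS summary statistics, and for sparse architectures
Bayesian continuous-shrinkage priors (horseshoe-type) are the standard
tool. Variants in different functional annotation categories, however,
contribute very differently to heritability — and the *category-level*
contribution can itself be sparse.

`prsbilevel` implements a PRS method with a **bilevel continuous shrinkage
prior**: every variant copy gets a local half-Cauchy scale `lambda_j`, and
every annotation group gets its own half-Cauchy scale `delta_k`, so the
prior on a standardized effect is

    beta_j ~ N(0, (sigma^2 / N) * delta^2_{A(j)} * lambda^2_j),
    delta_k, lambda_j ~ C+(0, 1),

with posterior inference by Gibbs sampling from GWAS summary statistics
(`beta_hat = G'y/N`) plus a block-diagonal LD reference (`D = G'G/N`) — no
individual-level training data. Overlapping annotations (e.g. pathways)
are handled by expanding a variant into one copy per group; multi-annotated
variants are shrunk less by construction. Group-wise scores
`PRS_k = sum_{j in k} G_j beta_tilde_j` are combined with weights `alpha_k`
estimated by 10-fold cross-validation on a separate validation cohort.

The package is written for statistical geneticists who build PRS from
summary statistics: it ships the estimator (`BilevelShrinkagePRS`), its
single-global-scale special case (`PRSCSAuto`, the K = 1 limit of the
model), a closed-form functional-prior comparator with posterior-effect
binning (`LDpredFunct`), the cross-validated score combiner, a synthetic
study generator (block-AR(1) genotypes, group-structured point-normal
effects, fixed-heritability phenotypes, marginal GWAS), and a CLI.

## Library use

```python
from prsbilevel import (BilevelShrinkagePRS, PRSCSAuto, read_sumstats,
                        read_annotations, read_ld_reference, align_alleles,
                        group_scores, fit_alpha_cv, combine)

ss = read_sumstats("sumstats.tsv", n_gwas=50_000)      # PRS-CS dialect TSV
blocks = read_ld_reference("panel", blocks=block_table) # PLINK triplet
ss = align_alleles(ss, blocks, panel_alleles)           # swap -> sign flip
am = read_annotations("annotations.tsv")                # variant -> groups

model = BilevelShrinkagePRS(random_state=1).fit(ss, blocks, am)
scores = group_scores(G_validation, model.posterior_)   # N x K matrix
w = fit_alpha_cv(scores, y_validation, trait="binary", seed=1)
prs = combine(scores, w)
```

Estimators follow scikit-learn conventions (`get_params`/`set_params`,
fitted attributes `beta_tilde_`, `delta2_mean_`, `predict`).

## Worked example (command line)

A reduced synthetic study — setting 1 of the packaged design, where four
annotation groups carry 0%, 0%, 10% and 90% of a 0.7 total heritability
over M = 2,500 SNPs (N_sumstat = 1,000, N_test = 480):

```bash
prsbilevel simulate --setting 1 --scale 0.02 --seed 7 --out sim
prsbilevel fit   --sumstats sim/sumstats.tsv --ld sim/ld.h5 \
                 --annotations sim/annotations.tsv --seed 7 --out fit
prsbilevel score --geno sim/test --effects fit/posterior.copies.tsv \
                 --pheno sim/phenotypes.tsv --trait quant --seed 7 --out score
prsbilevel evaluate --scores score/scores.tsv --pheno sim/phenotypes.tsv \
                 --trait quant --binarize top10 --out metrics.tsv
```

Output of the run above:

```
wrote setting-1 replicate to sim
wrote posterior effects for 2500 variants to fit
wrote scores for 480 individuals to score
{"n": 480, "r2": 0.5927585974589178, "auc": 0.9315200617283951}
```

and the fitted combination weights (`score/alpha.tsv`):

```
group   alpha
g1       0.184
g2      -0.091
g3       0.057
g4       1.867
```

The weights tell the story: the 90%-heritability group (g4) dominates the
combined score, the zero-heritability groups are weighted near zero. The
final score explains R² ≈ 0.59 of the held-out phenotype and separates the
top-decile "at-risk" individuals with AUC ≈ 0.93 (the evaluation here
scores the same cohort used to fit alpha; the per-fold held-out metrics are
in `score/fold_metrics.tsv`).

`prsbilevel compare --setting 1 --scale 0.02 --replicates 10 --seed 0 --out cmp`
runs the replicate-level method comparison (bilevel vs single-scale vs
hybrid) and writes a table of mean AUC/R² with 95% intervals.

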