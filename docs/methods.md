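# Methods

`wheatgs` re-creates, end to end and on synthetic data, a genomic-selection
study for wheat baking quality: unbalanced multi-trial phenotypes for eight
quality traits, mixed-model BLUEs and heritabilities, marker QC and a
genomic relationship matrix, single- and multi-trait prediction models,
three validation designs, and selection-response estimation.  This note
documents the models, the generator, the numerical choices, and what the
simulations can and cannot show.

## Phenotypic mixed models

Every trial is a completely randomised design.  The across-trial model is

    y_ij = mu + g_i + t_j + e_ij

with fixed trial effects `t_j`.  Genotypes are treated two ways, as is
standard in two-stage plant-breeding analysis: fixed, to produce BLUEs
(best linear unbiased estimates of line means), and random with
`g ~ N(0, I sigma_G^2)`, to estimate variance components by REML
(statsmodels `MixedLM`, random intercept per line).  The residual variance
confounds plot error and trial-by-line interaction; it is identified by the
replicated entries — mostly the check varieties that also connect the
trials.  A disconnected trial design is rejected with the offending trial
groups named (graph connectivity via networkx).

Heritability uses the mean variance of a difference (MVD) of the BLUEs,

    h2 = sigma_G^2 / (sigma_G^2 + MVD / 2),

which remains meaningful in severely unbalanced series.  The MVD is the
average over line pairs of `Var(BLUE_i - BLUE_j)`, computed from the
unscaled covariance of the fixed-genotype normal equations times the REML
residual variance; for panels above 500 lines a seeded random sample of
10,000 pairs replaces the full O(N^2) enumeration.  On a balanced design
this reduces to the classical `2 sigma_e^2 / r` (asserted against that
closed form in the tests).  Negative REML variances are clamped at zero, so
h2 always lies in [0, 1].  Trials in which no line is replicated get
`h2 = None` ("not estimable") and are retained in the across-trial fit;
estimable trials below the h2 threshold (0.1 by default) are dropped.  The
protein two-stage analysis fits each trial first, keeps trials with
h2 strictly above 0.3, and runs the across-trial model per year on the
stage-1 BLUEs.

Open design point: whether the across-trial MVD should be computed from
genotype-fixed BLUEs or genotype-random BLUPs is not determined by the h2
formula itself; this package uses fixed-effect BLUEs for the MVD and the
random-effect fit for the variance components.

## Marker QC and kinship

Markers are coded -1/+1 for the homozygotes and 0 for heterozygotes.
Filters (in this order, each counted separately): call rate >= 90 %, at
most 10 % missing, minor allele frequency >= 0.05 computed on non-missing
calls — a marker at exactly MAF 0.05 is retained, matching a
strictly-below removal rule.  Remaining missing calls are imputed per
chromosome by iterated conditional expectation under a multivariate-normal
model (three EM sweeps, stop early when the largest change is below 1e-4),
then clipped to [-1, 1]; a single-marker chromosome falls back to the
column mean.  LD pruning scans marker pairs in map order and drops one
member of every pair with r^2 > 0.8 by a seeded coin flip; after the scan
no retained pair exceeds the threshold (asserted by exhaustive rescan in
tests).  The genomic relationship matrix is

    K = W W' / (2 sum_k p_k (1 - p_k)),   W_ik = Z_ik + 1 - 2 p_k,

with `p_k` the +1-allele frequency on the current line set.  A printed form
of this denominator sometimes circulates with the sign flipped
(`2 sum (p_k - 1) p_k`); the positive convention above is the meaningful
one and is what this package computes.  A ridge of 1e-6 on the diagonal
keeps K invertible in the mixed-model solves; hand-example tests use
ridge 0.  For a near-inbred panel the mean diagonal of K is about 1 + f
with f close to 1 — the panel-level genetic variance among inbred lines is
(1 + f) times the base-population sigma_g^2, which matters whenever a
simulated variance ratio is compared with a REML estimate (see Simulation).

## Prediction models

**RR-BLUP** `y = Xb + Zu + e`, `u ~ N(0, I sigma_u^2)`: all (centred)
markers as random effects.  **G-BLUP** `y = Xb + Zg + e`,
`g ~ N(0, K sigma_g^2)`: the equivalent line-effect model; the shrinkage
ratio `lambda^2 = sigma_e^2 / sigma_g^2` is recorded per fit.  Both are
solved by one REML engine: eigendecompose the kernel once, profile the
restricted likelihood down to the single ratio, and maximise it by bounded
scalar search on the log scale (bounds e^-12..e^12, with an explicit
boundary comparison so a flat likelihood resolves to the boundary rather
than a spurious interior point).  Unphenotyped lines receive GEBVs through
the kinship block regression implied by the joint BLUP system
(`g_all = K[all, train] alpha`).  The RR-BLUP/G-BLUP equivalence (identical
GEBV rankings when K is built from the same markers) and the agreement with
direct Henderson mixed-model-equation solves to 1e-8 are regression-tested.

**W-BLUP** moves designated major-QTL markers (the glutenin-locus
analogues) from the random set into the fixed design, centred like the
random ones so the intercept stays interpretable; collinear fixed columns
are dropped with a warning.

**GWAS (K model)** estimates variance components once under the marker-free
null model and tests each mapped marker by generalised least squares under
that fixed covariance with Wald t-tests — the "population parameters
previously determined" scheme.  No genomic control or FDR machinery: the
downstream marker selection is rank-based (three smallest p-values, ties
broken by map position then marker id).  **MAS** is ordinary least squares
on the selected markers only, with pseudoinverse fallback for collinear
selections.

**Bivariate G-BLUP** (two traits, unstructured 2x2 Sigma_g and Sigma_e,
`g ~ MVN(0, Sigma_g (x) K)`) is fitted by EM-REML on Henderson's equations:
500-iteration cap, convergence when the relative restricted-log-likelihood
change falls below 1e-6 (1e-5 inside scenario resampling loops, where the
replicate average is insensitive to the last digits and the runtime is
not), PSD repair of the 2x2 estimates by eigenvalue clipping at 1e-8.  Two
numerically identical routes: a dense route for arbitrary missingness
patterns, and an O(n)-per-iteration route for complete data that works in
the eigenbasis of K, where the coefficient matrix is 2x2-block diagonal
plus a rank-2 border (agreement asserted to ~1e-9 in tests).  The residual
covariance between traits is estimated from co-observed lines and fixed at
zero when no line is observed for both.  Non-convergence raises an error
carrying the last estimates and the likelihood trace (callers in resampling
loops downgrade it to a warning).

**Selection index**: protein content is predicted for every line by
single-trait G-BLUP; those GEBVs `x_i` enter the target-trait model as a
fixed covariate, and the final score is `GEBV_i = x_i b_prot + g_i`.  The
`x_i` of training lines are in-sample predictions (the cross-validated
alternative is a sensitivity knob, not the default).  Optionally the
major-locus markers join step 2 as fixed effects — the combined
index/W-BLUP model used for the "enhanced genomic selection" strategy.

## Validation designs

Accuracy is always the Pearson correlation between GEBVs and observed
BLUEs; undefined correlations (fewer than 3 pairs, zero variance) are NaN
and excluded from means.  Sampling is simple and unstratified; k-fold
assignment is a seeded permutation cut into contiguous blocks.

The three-scheme suite resamples 80 % of the basis population into an
estimation set, runs the GWAS there, and evaluates every strategy under:
(A) fourfold CV *within* the estimation set with the marker selection held
fixed — the "inside trading" design, in which predictors were chosen before
the left-out observations were hidden, deliberately implemented as a
diagnostic of how badly that inflates accuracy; (B) prediction of the 20 %
left out before the GWAS; (C) forward prediction of disjoint later
populations.  Marker effects are refit per fold; only the selection is
frozen (the flaw under study is selection leakage, not effect-estimate
leakage).

The explained genetic variance of a candidate marker is estimated by
fivefold CV with 100 replicates: single-marker regression on the estimation
folds, adjusted squared correlation (`R2_adj = 1 - (1 - R2)(n-1)/(n-2)`,
one predictor) of predicted vs observed performance in the left-out fold,
averaged, divided by the trait heritability, clamped to [0, 1].  The
threshold sweep fixes in the W-BLUP model all candidates whose explained
variance exceeds each threshold from 0 to 25 % in 0.5 % steps and records
forward accuracy and marker count; with an empty fixed set it reduces —
exactly, not approximately — to the RR-BLUP baseline.  The operating
threshold reported in the sweep metadata is 5.00 % explained genetic
variance, a compromise between explained variance and marker number.

The multi-trait scenarios split the lines into validation, training, and
additional thirds; the target trait is observed on the training third only,
and protein content on the training third (TP), also the validation third
(VP), the training + additional thirds (ADD), or everywhere (FULL), against
the single-trait baseline (BASE).  Both the bivariate model and the
selection index are evaluated on each replicate repartition.

## Selection response

For a selected top fraction (ties broken by line id, "higher is better" by
default with a per-trait override):

    mu_hat_sel = mu + h2 (mu_sel - mu),      rho_rel = (mu_hat_sel - mu) / mu

with h2 = 1 for marker-assisted and genomic strategies and the evaluated
trait's heritability for direct and indirect phenotypic selection (the
quantity being shrunk is the observed superiority in that trait, whichever
criterion ranked the lines).  `mu` is the mean of the entire validation
population, which must be positive for the relative measure — a guard
rejects non-positive means.  The proportion of correctly selected lines is
the overlap of the predicted and true top fractions; for a random ranking
its expectation is the fraction itself (verified by permutation in tests).

## The synthetic-data generator

The generator emulates the study system rather than any particular dataset:

* **Panel**: a few hundred near-inbred lines (heterozygosity 2 % by
  default, matching F4:6+/doubled-haploid material), 1000–5000 biallelic
  markers on 21 chromosomes, MAF drawn uniformly from a configurable range.
* **LD**: within consecutive blocks (10 markers by default) a latent
  Gaussian with correlation `exp(-d / 5 cM)` is thresholded at each
  marker's allele frequency, so adjacent-marker r^2 decays with map
  distance; blocks and chromosomes are independent.  This reproduces the
  r^2-pruning regime with minimal machinery; it is not a coalescent or
  pedigree model and makes no claim about long-range LD or population
  structure (no subpopulations, no kinship stratification beyond what the
  random genotypes induce).
* **Traits**: eight quality traits — protein content plus seven dough
  rheological parameters — with default means, genetic and residual
  variances, and heritabilities (0.40–0.66) taken from published
  quantitative-genetic estimates for such material, and a dense genetic
  correlation network (e.g. 0.85 between protein and dough development).
  Three major glutenin-like loci on chromosomes 1–3 carry trait-specific
  fractions of the genetic variance, up to ~34 % (dough stability).
* **Exactness**: major-locus effects act through the marker residualised on
  the other major markers, so each locus's single-marker explained variance
  hits its target exactly in the realised panel; the polygenic background
  is a linear combination of the remaining markers, orthogonalised against
  the major loci and recoloured so the realised genetic covariance matches
  the target exactly.  Breeding values are therefore fully
  marker-determined — a requirement for kinship-based prediction to have
  the right operating characteristics.
* **Infeasibility of the published targets**: the published genetic
  correlation matrix is slightly indefinite as printed, and once the
  major-locus variance is carved out the remaining polygenic covariance is
  infeasible for some pairs (stability's major loci leave too little
  polygenic variance to support its printed 0.76 correlation with protein,
  which no generative model can satisfy simultaneously).  The generator
  projects to the nearest feasible matrix with the per-trait variances held
  fixed (Dykstra alternating projections on the correlation scale), so
  variances and locus fractions are exact while a few off-diagonal
  correlations move (protein–stability realises near 0.52).  Without major
  loci the realised covariance matches the target to machine precision.
* **Trials**: the first `n_checks` lines are check varieties replicated in
  every trial; other lines enter one (or `entry_reps`) plots in at least
  one trial each, so the design is unbalanced but always connected through
  the checks.  Trial effects are drawn with standard deviation equal to the
  genetic standard deviation (configurable); plot residuals are drawn
  per plot from the full residual covariance so residual correlations
  between traits survive.  Genotype-by-environment interaction is not
  modelled separately — it is confounded with the plot residual, as it is
  in the across-trial analysis itself.
* **Seeding**: one integer seed; every stage derives its own stream from it
  (CRC-based sub-seeding), so runs are bit-reproducible and stages are
  insensitive to each other's draw counts.

A heritability convention worth stating explicitly: "h2 = 0.5" for a
simulated phenotype can mean the variance ratio among the panel's lines or
the ratio in the GBLUP parameterisation.  Among inbred lines these differ
by the factor mean(diag K) ~ 1 + f ~ 1.9, and REML estimates the latter.
Parameter-recovery checks therefore calibrate the simulated noise on the
base-population scale.

What passing tests on this generator do **not** show: performance under
real population structure and family stratification, under LD between the
major loci and their chromosomal neighbourhoods' polygenic background
(deliberately removed for exactness), under non-Gaussian effect-size
distributions, or under genotype-by-environment interaction with structure
across years.  Reported accuracies are properties of the simulation, not
re-estimates of any published dataset's accuracies.

## Problem sizes and runtime choices

The analysis drivers default to a scaled study: 120 basis lines, three
forward populations of 40–50 lines, 120 protein-only additional lines, and
1200 markers — large enough for every qualitative contrast (inside-trading
inflation, W-BLUP benefit, VP > TP, genomic vs indirect response) while a
full run stays in the minutes range on a single core.  The dominant cost is
the bivariate EM in the masked scenarios (dense mixed-model equations,
~(2n)^3 per iteration); the complete-data eigenbasis route is orders of
magnitude faster and is selected automatically.  Resampling replicate
counts are parameters everywhere; the defaults favour a desk-scale run and
can be raised freely.

At small training sizes the multi-trait models can fall marginally below
the single-trait baseline even when the correlated trait carries no
information — the cost of estimating two extra covariance parameters.  This
is visible in the scenario outputs (deviations of a few hundredths at n of
a few hundred, shrinking with n), consistent with the general experience
that multi-trait prediction pays off only when the correlated trait brings
genuinely new information, e.g. protein records on the selection candidates
themselves or on a large set of additional lines.

## Known limitations

* Single-trait REML assumes one genetic variance component; no spatial or
  autoregressive within-trial correction (completely randomised designs
  only, by scope).
* The bivariate EM is limited to two traits; no Bayesian alphabet models,
  dominance, or epistasis.
* The inside-trading suite freezes marker *selection* per replicate but
  refits effects per fold; other leakage variants (e.g. frozen effects) are
  not implemented.
* `rho_rel` is undefined for traits with non-positive means; the guard
  rejects rather than rescales.
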