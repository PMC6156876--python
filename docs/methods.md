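# Methods

`nbdex` re-implements, as a tested pipeline, a differential-expression
analysis for a two-arm bovine RNA-seq design: a factorial skeletal-muscle
arm (two maternal diets x two sexes, ~24 calves) and a longitudinal blood
arm (steers sampled at 0, 3, 6 and 15 days post weaning, dpw).  Everything
operates on a gene x sample matrix of raw read counts plus a per-sample
design table; no alignment or quantification is performed.

## Count model

For gene g and sample s the raw count Y_gs follows an NB2 negative
binomial with log link:

    log mu_gs = x_s' beta_g + log L_s,        Var(Y_gs) = mu_gs + a_g mu_gs^2

where L_s is the TMM-normalized library size used as an offset and a_g the
per-gene dispersion.  The muscle mean model contains diet (CTRL/REST), sex
(steer/heifer), their interaction, sequencing batch, pen (nested in diet),
service sire, and the centered covariates RIN (RNA integrity) and DOT (dam's
days on dietary treatment).  The blood model replaces sex with time (a
4-level factor over 0/3/6/15 dpw) and its diet interaction, and has no pen
term.  Covariates are centered at the sample mean (R - Rbar, DOT - DOTbar)
so intercepts refer to an average-quality sample.

Pens nest within diet, so the pen dummy block spans the diet contrast.
Design matrices are reduced by order-preserving aliasing (a column is kept
only if it adds rank beyond the columns before it); treatment terms are
listed first and survive, and one redundant pen dummy per diet is dropped
and logged.  A consequence worth stating plainly: with pens nested in diet,
any real pen-level variation is partially confounded with the diet effect.
This is a property of the experimental design, not of the software.

## Normalization

Factors follow the canonical trimmed-mean-of-M-values recipe: the reference
sample is the one whose upper-quartile count fraction is closest to the
mean; per sample, log2 ratios (M) and average log2 abundances (A) are
computed over genes with nonzero counts in both sample and reference,
doubly trimmed (30% on M, 5% on A, rank-based) and averaged with
inverse-asymptotic-variance weights; factors are rescaled to multiply to 1.
The per-sample offset is the *normalized library size* L = (total counts) /
factor — the division convention is deliberate and kept as primary; the
more common effective-library-size convention (multiply) is available via
`convention="multiply"` in `prep.normalized_library_sizes`.

Genes with total count below 4x the number of samples are removed before
anything else; the filter is idempotent and boundary-exact (a row sum of
4n-1 is removed, 4n is kept).

## Dispersion estimation and squeezing

Genewise dispersions maximise a Cox-Reid-style adjusted profile likelihood,
APL(a) = loglik(beta_hat(a), a) - 0.5 log det(X'WX), with W the NB working
weights.  For speed the APL is evaluated for all genes at once on a 40-point
log-spaced grid (vectorised IRLS refits per grid point) and the per-gene
maximiser is refined by parabolic interpolation; the scalar bounded
optimiser is retained and the two agree to a few percent (pinned by test).
The global dispersion maximises the summed APL on the same grid.  Genewise
values are then squeezed toward the global value by a log-scale weighted
average with weights (residual df) : (prior df); `prior_df` defaults to 10.
`prior_df = 0` leaves estimates unshrunk, `prior_df = inf` uses the global
value everywhere.

## Fitting, model sets, AIC

Per-gene fits use Fisher-scoring IRLS at the squeezed dispersion;
coefficient covariance is the inverse expected information, and
AIC = -2 loglik + 2k with k the number of regression coefficients
(+1 when the dispersion was estimated from the gene alone).  Muscle
candidates: the full model, minus pen, minus the interaction, minus both
(4).  Blood candidates: {with, without diet-by-time interaction} crossed
with three residual structures {IND, CS, AR1} (6).  The selected model is
the converged candidate with minimal (pseudo-)AIC; ties go to fewer
parameters, then to the fixed candidate order.

Repeated blood measures are fitted in the GEE style: NB mean/variance with
a working within-animal correlation (compound symmetry, or AR1 over visit
indices 1-4 — visits are treated as equally spaced; the day values 0/3/6/15
are not used as lags).  rho is a moment estimate from Pearson residuals,
coefficients solve the weighted estimating equations, and the coefficient
covariance is model-based.  Because a GEE has no likelihood, the pseudo-AIC
is the working NB independence log-likelihood plus a Gaussian correction on
the Pearson-residual scale for the working correlation (exactly zero at
rho = 0), penalised by p + 1 for the correlation parameter.  This lets a
CS/AR1 candidate win when dependence is real while reducing exactly to the
ordinary AIC under independence.

## Tests, degrees of freedom, contrasts

Model terms are tested by Wald F statistics; 1-df planned contrasts by
Wald t.  Denominator degrees of freedom use Satterthwaite moment matching,
df = (sum a_k v_k)^2 / sum (a_k v_k)^2 / d_k over independent variance
components:

* independent-residual fits have one pooled working variance component, so
  df = n - p **plus the prior df of the dispersion squeeze**.  The credit
  matters: a squeezed dispersion behaves like a variance estimate with
  residual + prior degrees of freedom (as in moderated tests), and
  simulation shows the Wald statistic with a known dispersion is already
  close to chi-squared calibrated — using n - p alone makes tests
  noticeably conservative at n ~ 23;
* CS/AR1 fits moment-match over per-animal score contributions to the
  contrast variance, reflecting that animals, not samples, are the
  independent replicates.  Degenerate variances floor the df at 1 with a
  warning.

The planned contrasts over the blood time levels (0, 3, 6, 15 dpw) are
vaccination = (1/3, 1/3, 1/3, -1) (average of days 0-6 vs day 15) and
weaning = (1, -1/2, -1/2, 0) (day 0 vs average of days 3 and 6); their
interaction versions apply the same weights with opposite sign across the
two diets.  Contrast vectors are built from synthetic design cells with
nuisance factors at reference and covariates at 0, so any weight vector
summing to zero cancels all nuisance columns.  Fold changes are
FC = exp(estimate) with 95% CI exp(estimate +- t_{df,0.975} SE); FC > 1
means up-regulated in REST (or in females for the sex effect).

## Multiple testing and DEG calling

Benjamini-Hochberg q-values are computed per model term across genes (not
jointly across terms); NaN p-values from non-converged or untestable genes
are excluded from m.  DEG are called at q <= 0.05.  Contrast-based DEG use
the two-stage rule: gate on the interaction (or time main effect) q <= 0.05,
then require the contrast's unadjusted p < 0.05.  Volcano tables drop rows
with FC outside [1/5, 5] or q < 1e-6; Venn summaries report all disjoint
region counts.

## Networks

Expression is adjusted to the sum of the estimated diet component and the
residual, on the working (linearised) scale of the fit: adjusted value =
X_diet beta_diet + (y - mu)/mu.  "Adjusted counts" cannot be literal counts
once multiplicative effects are removed, hence the linear-predictor scale.
Partial correlations come from the Moore-Penrose pseudoinverse P of the
gene-gene correlation matrix (pcor_ij = -P_ij / sqrt(P_ii P_jj)); the
pseudoinverse handles the typical p > n case (e.g. 100+ DEG vs ~23 samples)
and equals the plain inverse when the matrix is well-conditioned.  An
optional shrinkage blend toward the identity exists but is off by default.
Edges require |pcor| strictly > 0.8.  Cross-tissue networks must be built
on a common sample set (steers, with a chosen blood time point); the caller
restricts the samples and the graph records the flag.

## Enrichment

A local over-representation test replaces any external web service: per
term, observed = |DEG ∩ term|, expected = |DEG| |term| / |background|,
fold enrichment = observed/expected, two-sided Fisher exact p from the 2x2
table.  P-values are deliberately unadjusted (flagged at p < 0.05) and no
ontology-graph propagation is attempted.  Annotations are read from GMT.

## The synthetic generator

The generator emulates the study conditions: muscle 2 diets x 2 sexes x 6
calves (24 samples; optionally one dropped to mirror the RIN < 8 exclusion,
giving the study's 23), 5 pens per diet, 2 batches, 2 sires, RIN uniform on
[8, 10], DOT normal (40, 5.1 days); blood 12 steers x 4 visits with a
Gaussian copula inducing AR1/CS within-animal dependence (latent MVN pushed
through NB quantiles — exact NB2 marginals, controllable dependence; lag-2
latent correlation is rho^2 by construction and is verified via the
Spearman-to-Gaussian mapping).  Per-gene dispersions are log-normal around
a global a = 0.1 (spread 0.3); library sizes are uniform on a configurable
range (default 1-2 million over a 2,000-gene universe, i.e. study-like
per-gene depth at a desk-scale gene count); baseline abundances are
log-normal and sum-normalised so a sample's expected total equals its
library size, which makes the offset property (double the depth, double
every gene's expectation) exact.  Configurable fractions of genes carry
diet/sex/time/interaction effects with log fold changes drawn N(0, 0.5^2)
on the natural-log scale — the magnitude is a convention, stated nowhere in
the study.  Nuisance magnitudes default to modest values (batch 0.1, pen
and sire 0.05 log-SD, small covariate slopes).

What the generator does *not* emulate: sequence content, mapping artefacts,
gene-length effects, correlated gene modules (genes are independent given
the design), or library-composition bias beyond depth.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
assumed model, not robustness to real-data pathologies.

## Calibration, and what select-then-test does

Under a global null (all effect proportions zero and nuisance magnitudes
zero — pens nest in diet, so nonzero pen effects would make the diet null
false by design) the term tests on the full-model fit are calibrated:
type-I error 0.049-0.057 at nominal 0.05 with n = 23, and BH at q <= 0.05
yields essentially zero discoveries (mean ~0.15 DEG per 2,000-gene
replicate across 20 replicates).

The pipeline proper follows the original procedure: select a model per gene
by AIC, then test terms inside the selected model.  This is *post-selection
inference* and is not calibrated — the interaction term, tested only in
genes where AIC kept it, shows ~0.3 empirical type-I error under the null,
and the realised false-discovery proportion of pipeline diet calls exceeds
the nominal q when nuisance pen effects are present (pen-diet confounding).
Both behaviours are faithful to the select-then-test design; users wanting
calibrated inference should test terms in the full model.

## Numerical choices and degenerate inputs

Linear predictors are clipped to [-30, 30]; IRLS starts from a least-squares
fit to log(y + 0.5) - offset and declares convergence on joint
log-likelihood and step tolerance; non-converged candidates are excluded
from selection, and a gene with no converged candidate is flagged and
skipped.  Dispersion grid bounds are [1e-6, 10] with parabolic refinement.
rho estimates are clipped to [-0.95, 0.95]; empty trim sets in TMM fall
back to no trimming; a sample sharing no expressed gene with the TMM
reference gets factor 1 with a warning.  AIC ties are resolved toward fewer
parameters, then candidate order (both stated, both tested).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `prior_df` | 10 | weight of the global dispersion in the squeeze; also the df credit in tests |
| `trim_m`, `trim_a` | 0.30, 0.05 | TMM double-trim fractions |
| `alpha` | 0.05 | DEG threshold on q; contrast stage-2 threshold on p |
| network `threshold` | 0.8 | strict lower bound on absolute partial correlation |
| `convention` | "divide" | offset convention for normalized library size |
| `fc_clip`, `q_clip` | 5, 1e-6 | volcano display clipping |

Problem sizes used by the test suite and the acceptance script (2,000-gene
null replicates, 1,000-gene end-to-end runs, 200-animal recovery checks)
were chosen as the smallest sizes at which the Monte-Carlo error is clearly
inside the asserted bands.
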