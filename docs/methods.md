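# Methods

This note documents the models implemented in `rapagen`, the assumptions
behind them, what the synthetic data emulate (and do not), and the
numerical choices a user may want to audit.

## Developmental-delay phenotype

Pupation is recorded as per-vial counts of new pupae per observation day.
Per line, batch and condition, the mean pupation time is the count-weighted
mean observation day pooled over vials, with SD on the pupa-level day list
(denominator n-1). Recorded days are treated as exact; no
interval-censoring correction is applied for sub-daily observation. The
delay is `mean(rapamycin) - mean(control)`; negative delays are legitimate
(slightly faster development on drug). The pooled SD uses the standard
two-sample denominator `n_r + n_c - 2`; the pooled SE multiplies by
`sqrt(1/n_r + 1/n_c)`.

Normalization for association proceeds in four steps: shift by +1 so all
values are positive; Box-Cox with one global lambda chosen by profile
log-likelihood (grid on [-2, 2] step 0.01, then Brent refinement in the
best bracket); within each batch, subtract the mean transformed value of
the four reference lines present in every batch; divide by the SD of the
centred values over *all* lines in the batch (centre-on-references,
scale-on-batch — the scaling set is a design choice; using only reference
lines would estimate the SD from four points). A zero batch SD is reported
as degenerate rather than divided through.

## SNP heritability by gBLUP/REML

Genotypes are homozygous allele doses {0, 2}; heterozygote calls in PLINK
input are treated as missing (inbred-line convention). Two QC profiles are
configured by default: the GRM profile (MAF >= 0.05, call rate >= 0.95,
then LD pruning at r2 <= 0.8 in 200 kb windows sliding 5 kb) and the scan
profile (MAF > 0.05, call rate > 0.80, strict inequalities, no pruning).
Missing doses are imputed once to the marker mean, before both GRM and
scan. The GRM is K = W W'/m over mean-centred, unit-SD (population
denominator) doses.

The model `y = X beta + g + e`, `g ~ N(0, K sg2)`, `e ~ N(0, I se2)` is
estimated by REML: K is eigendecomposed once, the restricted likelihood is
profiled over lambda = sg2/se2 (se2 has a closed form at fixed lambda), and
lambda is optimized on natural-log lambda in [-10, 10] by a 41-point grid
plus bounded Brent. A boundary flag marks optima pinned at the bracket
edge. Fixed effects are GLS at the optimum; BLUPs are
`ghat = sg2 K V^-1 (y - X beta)`. The SE of H2 comes from the numerical
Hessian of the restricted likelihood in (sg2, se2) with a delta-method
transform — an approximation, adequate for the wide confidence statements
it supports.

Resampling: the bootstrap-style uncertainty curve subsamples lines
*without* replacement (duplicated lines would make K singular);
permutations shuffle y against (X, K) jointly held fixed, breaking both
covariate and kinship association. The empirical p is
`#(H2_perm >= H2_obs)/n_perm`, reported at the floor `1/n_perm` (flagged)
when no permutation reaches the observed value.

## Marker and set association (CVAT)

Marker effects are backsolved from the BLUPs, `s = W' K+ ghat / m`, with a
pseudo-inverse for rank-deficient K, so `W s` is the projection of `ghat`
onto the marker space. The single-marker scan regresses `ghat` on each
scaled dose (t with n-2 df, two-sided), vectorized in one pass.

The CVAT statistic of a feature is `T = sum_i cov(ghat, W_i s_i)` over its
member markers (sample covariance, n-1). Summed over all markers with a
full-rank K this reproduces var(ghat) exactly — a decomposition identity
the tests assert at 1e-8. The permutation null draws random marker subsets
of matched size without replacement and sums their contributions; because
the statistic is additive over markers this is exact to vectorize
(random-key argpartition in memory-bounded chunks; 10^5 permutations on
10^4 markers in seconds). The test is one-sided: large positive covariance
indicates association. Genotype-rotation nulls were considered and not
implemented; the null scheme is isolated in `cvat_null` so it can be
swapped.

Features are built from 1-based closed transcript intervals (BED-style
0-based half-open input is converted on read): gene level takes markers
with `start <= pos <= end`, the widened level extends both ends by 1 kb,
and pathways union their member genes' marker sets, dropping pathways with
fewer than two genes with markers or fewer than 200 total markers (both
configurable). A marker inside several genes counts in every containing
feature. Gene-level features need only one marker.

In the end-to-end pipeline the GRM comes from the pruned GRM-profile set
while marker effects, the scan and CVAT features use the larger
scan-profile set (`s = W_scan' K+ ghat / m_scan`); the exact decomposition
identity holds when both use the same marker set, which the unit tests
exercise separately.

Storey q-values: pi0 is estimated on the lambda grid 0.05..0.95 (step
0.05) with a natural cubic spline evaluated at 0.95, clipped to (0, 1];
with fewer than 10 p-values pi0 = 1. q-values use the step-up cumulative
minimum, reducing exactly to Benjamini-Hochberg at pi0 = 1.

## Metabolome analysis

Raw intensities must be positive; they are log_e transformed and each
sample row centred and scaled to SD 1 (n-1 denominator). Note a
consequence verified in the tests: a treatment effect common to *all*
metabolites is removed by per-sample standardization — effects are
estimated relative to the sample's overall profile.

Batch correction reimplements the parametric empirical-Bayes
location/scale scheme with no covariate matrix: per-metabolite
standardization against batch-design fitted means and pooled variance
(population denominator), batchwise location/scale estimates shrunk toward
a normal / inverse-gamma prior by the iterative moment algorithm
(tolerance 1e-6, max 100 iterations), adjustment, and restoration of the
metabolite scale. One test cross-checks the whole routine against the
reference R implementation (`sva::ComBat`) to 1e-6.

Per-metabolite inference uses a random-intercept-per-line mixed model fit
by the same eigen-REML core as the genomic analyses with K = Z Z' over the
line incidence. Fixed effects use sum-to-zero (+-0.5) coding so each 1-df
term's Type-III test is the Wald F on its coefficient,
`F = beta^2 / Var(beta)` against denominator df `n - rank(X)`. With a zero
line variance this reduces exactly to fixed-effects-only Type-III ANOVA
(asserted against statsmodels); Satterthwaite/Kenward-Roger df are *not*
implemented — the choice is validated instead by null-simulation
calibration of the interaction term (pooled type-I error 0.050 over 2,000
null metabolites at the study design). Within-class treatment effects use
control = 0 / rapamycin = 1 coding so beta_T is the drug shift; q-values
are computed per term across metabolites. Sign concordance between classes
is Spearman's rho with average ranks and the t approximation.

PCA operates on the per-sample-normalized, batch-corrected matrix with
metabolites as variables, centred, with no further column scaling (the
scaling already happened per sample); components are oriented so each
one's largest-magnitude loading is positive.

## Starvation axis

Harmonization order: drop reference metabolites with more than one missing
value; impute single-missing metabolites by 10-nearest-neighbour means
(neighbours are *metabolites*, Euclidean distance over pairwise-complete
samples, donors restricted to metabolites observed at the missing sample);
per-sample centre/scale the reference; z-score and average declared
duplicate-ion column pairs; intersect with the query by the name map. Two
reference columns mapping to one query name outside the declared pairs is
an error. Filtering precedes duplicate-ion averaging, matching the order
in which the steps are defined.

The axis is PC1 of the harmonized reference, oriented so training scores
increase with starvation time (positive Spearman correlation); warnings
fire when PC1 explains under 10% of variance or the score-time correlation
is weak. The trajectory `s(t) = a t/(t+b) - c` is fit by bounded
least squares (b > 0) from `a0 = range(scores)`, `b0 = median(times)`,
`c0 = -min(scores)` plus five jittered restarts; `r2 = 1 - SS_res/SS_tot`;
the fitted curve passes through -c at t = 0 by construction. Projection
subtracts the *reference training means* before applying loadings (standard
PCA projection; a raw dot-product switch exists). Displacement is tested
with the same mixed-model machinery (PC ~ T + P + TxP + (1|line)).

## Synthetic data: what it emulates, and what it does not

Genotypes: fully inbred lines as homozygote doses {0, 2}; LD by
first-order Markov copying along each of five chromosome arms (copy the
previous marker's allele with probability `ld_decay`, else draw fresh at a
MAF uniform on the requested range). The default `ld_decay = 0.9` gives
the strong local LD of a dense panel variant set; it also gives the GRM
the eigenvalue spread that makes variance components identifiable at a few
hundred lines — with near-independent markers K approaches the identity
and H2 is unidentifiable regardless of estimator quality. This is Markov
copying, not a coalescent: it produces no long-range structure, no
population stratification and no realistic allele-frequency spectrum.

Phenotypes: `y = X beta + W b + batch + e` with the genetic and residual
components rescaled to empirical SDs sqrt(h2) and sqrt(1-h2), so the
realized variance fraction equals the requested h2 essentially exactly.
The default architecture is fully polygenic (all markers causal), matching
the gBLUP model; `causal_features` with `feature_variance_share`
concentrates a chosen fraction of genetic variance in a feature for power
studies. Pupation records round Gaussian development times to days, with
binomial survival thinning (default 0.5, consistent with a screen
recovering ~77 pupae per condition from 4 vials x 40 embryos).

Metabolomes: log-scale line/treatment/class/interaction effects plus
batch location/scale distortion, exponentiated to a raw positive scale;
the default design is six resistant and seven sensitive lines, both
treatments, two extraction batches. The starvation generator drives
metabolites through a shared loading vector from the saturating latent
trajectory (default constants a = 20.53 h-score, b = 2.77 h, c = 10.01),
with optional missing-value and duplicate-ion injection.

Because the generators satisfy the estimators' assumptions (Gaussian
effects, correct model form), passing recovery tests demonstrates
correctness of the implementation, not robustness to real-data pathologies
(non-Gaussian error, shared-environment confounding, genotype errors,
LC-MS drift within batch).

## Problem sizes and calibration checks

The validation suite runs: heritability recovery at 200 lines x 5,000
markers, 25 seeds per true h2 in {0.2, 0.5, 0.8} (mean within +-0.10);
permutation calibration on 80 lines x 600 markers, 600 null replicates x
99 permutations (the procedure is rank-exact; 600 replicates make the
Monte-Carlo estimate of the 5% rate tight); CVAT type-I over 10^3 random
features and power over 25 panels of 300 lines x 2,000 markers with a
100-marker pathway carrying half the genetic variance; metabolome checks
at the study scale (52 samples x 154 metabolites; type-I pooled over four
500-metabolite null datasets). `scripts/acceptance.py` repeats these at
slightly reduced replicate counts and prints the measured quantities.

## Known limitations

- Single variance component only: no dominance, no multiple GRMs, no
  mitochondrial haplotype grouping.
- H2 SE is a Hessian approximation; near-boundary estimates get NaN SEs.
- The CVAT null ignores LD between a feature's markers and the rest of the
  genome (matched-size random sets); enrichment of very large features in
  high-LD regions could shift calibration on real data.
- Mixed-model df are residual-based, not Satterthwaite; fine at the
  designs tested, anticonservative for severely unbalanced line structures
  on between-line terms.
- kNN imputation distances are raw Euclidean sums over shared samples, not
  normalized per observation count.
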