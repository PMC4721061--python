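# Methods

## The phenotype and the study design

The hypertriglyceridemic-waist (HTGW) phenotype is the conjunction of high
waist circumference (>= 90 cm in males, >= 85 cm in females) and high fasting
triglycerides (>= 2.0 mmol/L in males, >= 1.5 mmol/L in females), with all
comparisons inclusive. The cut-offs are configurable in `scan.make_htgw`; the
defaults above are the package's authoritative definition. The analyses run
on extended pedigrees — by default 39 three-generation families totalling
about 850 individuals — where relatedness both enables heritability
estimation and invalidates ordinary regression, so every association model is
a variance-component ("polygenic") model.

## The polygenic model

For a trait vector y with covariate matrix X and additive relationship
matrix A (twice the kinship matrix, built by the tabular recursion in
`pedigree.relationship_matrix` with founders assumed unrelated and
non-inbred),

    y ~ MVN(X b,  sigma2_g A + sigma2_e I),
    h2 = sigma2_g / (sigma2_g + sigma2_e).

Estimation is maximum likelihood, not REML, so that likelihood-ratio tests
between nested fixed-effect models are coherent. A is eigendecomposed once
(blockwise by family — A is block-diagonal, so this is exact and fast) and
y, X are rotated into the eigenbasis where the covariance is diagonal. For
fixed h2, b is profiled out by GLS and the total variance in closed form,
leaving a one-dimensional profile likelihood in h2 which is maximised on
[0, 1] by a 21-point grid followed by bounded Brent refinement in the
bracketing interval (xatol 1e-10). The grid covers the multi-start points
{0.1, 0.5, 0.9} and makes the optimiser deterministic and boundary-safe. A
flat profile (range < 1e-8) or fewer than two residual degrees of freedom is
flagged as non-convergence; flagged fits carry a message and are never
silently dropped.

Tests:

* heritability, H0: h2 = 0 — LRT against the h2 = 0 refit, referred to the
  boundary mixture 0.5*chi2_0 + 0.5*chi2_1 (a zero statistic gives p = 0.5);
* a fixed effect — LRT between fits with and without the focal column,
  variance components re-estimated under both, referred to chi2_1. An
  all-zero focal column short-circuits to (b = 0, p = 1).

## Binary traits: the liability-threshold model

A binary trait is modelled as the indicator of a latent standard-normal
liability exceeding the threshold t = Phi^-1(1 - K) at prevalence K, with
the polygenic covariance on the liability scale. The package fits the 0/1
indicator with the same linear mixed model on the observed scale and maps
estimates to the liability scale with the classical threshold-model factors:

    b_liab  = b_obs / phi(t),
    h2_liab = h2_obs * K (1 - K) / phi(t)^2,

where phi is the standard normal density and K is taken from the sample (or
supplied). Likelihood-ratio tests are performed on the observed scale, where
they are valid irrespective of the trait distribution; the scale conversion
affects only reported coefficients, not p-values. This design was chosen
over a pairwise composite probit likelihood because the observed-scale LRT
is exactly calibrated (verified by the null-simulation suite: heritability
LRT and per-marker scans hold their level), whereas a composite-likelihood
ratio is not chi-square distributed without a Godambe-type adjustment, and
because the scan needs thousands of per-marker refits, which the
eigen-rotated path delivers in milliseconds. The conversion is accurate for
small effects and moderate prevalence; at high liability heritability
(h2 >~ 0.7) it overstates h2 by a few hundredths (the linear approximation
degrades), which is a known property of the transformation, not an
implementation artefact. At the default study conditions (h2 = 0.52,
K = 0.26) the bias is about +0.02.

In the simulator the liability threshold is the *empirical*
(1 - K)-quantile, not the normal quantile, so the realised prevalence is
exact at finite n.

## Bivariate decomposition

Two continuous traits are modelled jointly with genetic covariance
rho_G sqrt(s2_gi s2_gj) A and environmental covariance
rho_E sqrt(s2_ei s2_ej) I. In the eigenbasis of A the likelihood factorises
into per-eigencomponent 2x2 Gaussians, so evaluation is O(n); both traits'
fixed effects are profiled out by joint GLS at every covariance evaluation.
The four variances are searched through log transforms and the two
correlations through atanh transforms (Nelder-Mead, three h2 starts), which
keeps the search interior; trial covariances that are numerically singular
are penalised, which reprojects the optimiser into the feasible region. The
implied phenotypic correlation

    rho_P = rho_G sqrt(h2_i h2_j) + rho_E sqrt((1 - h2_i)(1 - h2_j))

is computed from the fit's own fields, so the identity holds to machine
precision by construction; the model-free companion (Pearson correlation of
covariate-adjusted residuals) is reported alongside. rho_G = 0 and rho_E = 0
are tested by constrained refits and chi2_1 LRTs. When two traits are
numerically identical the joint covariance is singular and only rho_P = 1 is
identified; the individual correlations sit at a boundary.

## Marker scans, genomic control, FDR

Methylation beta values are rank-transformed before association
(z = Phi^-1((rank - 0.5)/n), average ranks for ties), which fixes the
marker scale and neutralises skew; SNPs enter as 0/1/2 dosages. The scan
shares one eigendecomposition and one reduced (no-marker) fit across all
markers; each marker adds one column and is tested by the chi2_1 LRT.
Per-marker convergence failures are recorded and excluded from the corrected
set, never silently dropped.

The genomic inflation factor is lambda_median = median(chi2) / 0.4549
(the chi2_1 median). Nominal p-values are corrected by mapping to chi2_1
statistics, dividing by lambda, and mapping back — but only when lambda > 1:
deflating p-values when lambda < 1 would manufacture significance, so
deflation is never applied. Benjamini-Hochberg q-values (step-up, monotone,
capped at 1) are attached to the corrected p-values; the significance
threshold is FDR 0.05.

Probe QC removes, in order: sex-chromosome probes, non-CpG probes,
SNP-assay probes, model-convergence failures, then probes with detection
p > 0.01 in > 5 % of samples (both inequalities strict — a probe failing in
exactly 5 % of samples is retained). SNP QC keeps call rate >= 0.97,
MAF >= 0.05 and Hardy-Weinberg exact p >= 0.001, all inclusive; the HWE test
is the exact conditional enumeration over heterozygote counts and is
computed on founders only, because genotype frequencies among relatives do
not follow HWE sampling assumptions. Ancestry principal components are the
top eigenvectors of column-standardised dosages with a deterministic sign
convention (largest-magnitude loading positive).

The odds ratio for a liability-scale coefficient is OR = exp(sqrt(pi) * b),
with b oriented so that positive values increase risk; sqrt(pi) ~ 1.772 is
the probit-to-logit scaling, and CI bounds transform identically.

## Mediation and model information

Sobel mediation fits two polygenic models — mediator ~ site + covariates
(path a) and outcome ~ mediator + site + covariates (path b) — and reports
the product a*b with the delta-method standard error
sqrt(a^2 s_b^2 + b^2 s_a^2) and a normal-approximation p. The z statistic is
symmetric in the two paths. The normal approximation is accurate when at
least one path is strongly determined; under the complete null (both paths
zero) the Sobel test is, as is well known, extremely conservative, so the
calibration suite evaluates its level under the realistic no-mediation null
(no site -> mediator path, strong mediator -> outcome path), where the
empirical level is nominal.

Model information is compared by the likelihood-based Kullback-Leibler

    R^2 = 1 - exp(-2 (logL_full - logL_null) / n),

which reduces exactly to the OLS R^2 for Gaussian linear models (this
equivalence is the definition's justification and its test). The
forward-stepwise ladder takes the intercept-only polygenic model as the R^2
null, adds sites one at a time, and reports per-step gains and chi2_1 LRT
p-values; the step gains sum to the total gain exactly. A site collinear
with the current design adds zero information (delta R^2 = 0, p = 1,
annotated) rather than failing the ladder.

## Agreement statistics

Bland-Altman limits of agreement are mean(d) +/- 1.96 sd(d) for paired
differences d = method2 - method1 (1.96, not 2.0). Pitman's paired test of
unequal variances is the correlation of (d, method1 + method2) referred to
t on n - 2 degrees of freedom; exactly-constant differences make this 0/0
and raise a degenerate-input error. Spearman's correlation uses average
ranks with the t-approximation p.

## The synthetic cohort: what it emulates and what it does not

`simulate.SimConfig` defaults are the study conditions: 39 extended
three-generation families, ~850 individuals (realised size nudged to within
5 % of target by adding/removing leaf grandchildren), waist/triglycerides as
a bivariate polygenic pair with (h2_waist, h2_tg, rho_G, rho_E) =
(0.30, 0.20, 0.07, 0.32), HTGW as their sex-thresholded conjunction with
marginal crossing rates ~55 %/~40 % giving ~26 % joint prevalence, T2D as a
second threshold trait (prevalence 20 %) loading on the shared waist/TG axis
plus its own polygenic liability, a 2,000-probe methylome, and 1,000 SNPs
with MAF uniform on [0.05, 0.5] produced by Mendelian gene dropping through
the pedigree.

Methylation is generated on the logit scale — probe baseline (uniform on
0.08-0.92) + polygenic component (30 % of a 0.15-SD probe noise budget) +
planted trait effect + chip/position batch effects (SD 0.05/0.025) +
cell-fraction loadings (five Dirichlet components: CD4+ T, CD8+ T, B, NK,
granulocytes) + residual noise — and mapped through the logistic function,
so beta stays in (0, 1). Effects are planted as
logit(m + delta) - logit(m) on the affected group, so the realised
median-beta group difference matches the configured delta (the median
commutes with the monotone logistic map); the three default sites use
deltas of -0.010, -0.011 and +0.016. Detection p-values are < 0.005 for
clean probes, with a configurable 0.3 % of probes failing (> 0.01) in more
than 5 % of samples. Annotation marks ~2.4 % of probes as sex-chromosomal,
~0.6 % as non-CpG and ~0.1 % as SNP-assay so the filters are exercised.

Deliberate simplifications, hence what passing tests do and do not show:
no linkage disequilibrium between SNPs; covariates (age, blood pressures,
BMI) have normal marginals with plausible means/SDs, without claiming
distributional realism; no population admixture beyond what the PC
machinery can be tested on separately; probe chemistry (Infinium I/II) and
within-array normalisation are out of scope — beta values are taken as
already normalised. One structural consequence worth stating: because the
cohort's HTGW is *derived* from its components, its liability heritability
is implied by the component h2 values (roughly 0.1-0.2 under the defaults),
not independently settable; the 0.52-heritability condition is therefore
exercised on directly simulated threshold traits
(`simulate_polygenic_trait` + `simulate_binary_trait`), which is also how
the parameter-recovery checks are defined. A cohort cannot simultaneously
have component heritabilities of 0.30/0.20 with near-zero genetic
correlation and a conjunction heritability of 0.52 under this generative
model; the package makes that tension explicit instead of hiding it.

All generators are deterministic under a fixed seed (`numpy` Generator
seeded per component), and written cohorts round-trip through the TSV
readers losslessly up to text precision.

## Calibration designs and problem sizes

The suite verifies, at the sizes given, all chosen as the package's own
reduced-scale designs:

* heritability-LRT level: 500 null replicates at the full 39-family design
  (the boundary mixture needs the full family count; with ~10 families the
  test is conservative, rate ~0.02);
* Sobel level: 500 replicates at the full design under the no-mediation
  null with a strong mediator -> outcome path;
* scan calibration: 500 null scans of 40 probes at a 10-family (~230
  individual) design with age + sex covariates; lambda_median is pooled
  over all 20,000 null statistics because a per-scan median over 40 values
  has sampling SD ~0.3 and cannot be bounded meaningfully, and the
  false-discovery proportion is averaged over scans;
* parameter recovery: 50 replicates at the full design for h2 in
  {0.2, 0.52, 0.8} (continuous), the binary trait at (0.52, 26 %), and the
  bivariate split (0.30, 0.20, 0.07, 0.32).

## Known limitations

Marriage loops and inbreeding are handled by the tabular recursion (the
diagonal rises above 1) but the simulator never generates them; dominance
and household components are not modelled; bivariate fits are
continuous-continuous only; the liability conversion degrades above
h2 ~ 0.7 as noted; and the ML small-sample bias slightly inflates scan
statistics when the covariate count approaches n (at the default design,
~95 covariates against n ~ 850, lambda_median runs ~1.05-1.10 without any
true signal, which the genomic-control step absorbs).
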