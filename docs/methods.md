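# Methods

## Model

The toolkit fits a single-trait reaction-norm mixed model. For individual
*i* with standardized environmental covariate *c_i* (mean 0, SD 1, sample-SD
convention):

    y_i = mu + alpha0_i + alpha1_i c_i + tau0_i + tau1_i c_i

* the genetic intercept/slope pair (alpha0, alpha1) is multivariate normal
  across individuals with covariance kernel K (the genomic relationship
  matrix) and 2x2 parameter block G = [[s2_a0, s_a01], [s_a01, s2_a1]];
* the residual pair (tau0, tau1) is independent across individuals with
  block T = [[s2_t0, s_t01], [s_t01, s2_t1]].

s2_a1 is the GxE variance and s2_t1 the RxE variance; the covariances
s_a01, s_t01 are part of the interaction blocks (the standard
random-regression parameterization), so each interaction block contributes
2 degrees of freedom to the model comparisons. The phenotypic covariance is

    V = s2_a0 K + s_a01 (K o (c1' + 1c')) + s2_a1 (K o cc') + D,
    D_ii = s2_t0 + 2 s_t01 c_i + s2_t1 c_i^2.

Four nested specifications are fitted: NULL (s2_a0, s2_t0 — ordinary
GREML), GXE_ONLY (+ s_a01, s2_a1), RXE_ONLY (+ s_t01, s2_t1), FULL (all
six). Fixed effects inside the REML are an intercept only: all other
adjustment (including the covariate's own mean effect, which would
otherwise masquerade as interaction) is regressed out of the phenotype
beforehand, and the adjusted trait is outlier-screened at +/-3 SD and
mapped to normal scores before fitting (order: adjust → outlier QC →
inverse normal transform, recorded in a provenance trail).

## Estimation

Restricted likelihood: logL = -(log|V| + log|X'V^-1X| + y'Py)/2 with X = 1;
additive constants are omitted since every use is a model comparison.
Optimization is average-information (AI) REML:

* score_k = -(tr(P dV_k) - y'P dV_k P y)/2, AI_kl = (dV_k Py)' P (dV_l Py)/2,
  with P formed from an explicit Cholesky-based inverse; because every
  dV_k is either a Hadamard-masked K or diagonal, all traces are O(n^2) and
  each iteration costs one O(n^3) factorization.
* First step is a conservative EM-flavoured scaled-gradient move; later
  steps are AI-Newton with step-halving (30 scales) and, if the AI
  direction fails entirely, a retry along the raw gradient.
* Starting values: half the phenotypic variance on each intercept variance,
  0.01x phenotypic variance on free interaction parameters; max 100
  iterations.
* Estimates are **unconstrained** by default (variances may go slightly
  negative). This keeps likelihood-ratio statistics chi-square calibrated
  under the null; the legitimacy rule (below) handles estimates outside the
  legitimate parameter space.

Convergence is declared when the likelihood has stabilized: |dlogL| < 1e-6
together with either gradient norm < 1e-4 or a second consecutive small
step, or when no uphill step exists along either search direction. A pure
gradient criterion is deliberately not required: under null data the
unconstrained optimum frequently sits on the boundary of the
positive-definite region, where logL approaches a supremum but the gradient
does not vanish; the likelihood value — the only quantity the tests use —
does stabilize there. The gradient norm is retained as a diagnostic on
every fit.

Nested fits are chained (`fit_nested_models`): each interaction model warm
starts from the NULL optimum and the FULL model from the better
single-interaction optimum (refitting from the other when the first attempt
fails to dominate), which enforces the nesting inequality
logL(FULL) >= logL(reduced) by construction.

A constrained mode (`RemlOptions(constrain=True)`) reparameterizes each
2x2 block by its Cholesky factor — making positive semidefiniteness
automatic — and maximizes by Nelder-Mead with restart polish. It exists for
small-sample work: with a few dozen individuals the *unconstrained*
likelihood is effectively unbounded along ridges approaching the singular-V
boundary (negative variance estimates that keep V barely positive
definite), so only the constrained optimum is well defined there. Default
inference always uses the unconstrained mode.

BLUPs are conditional means at the REML estimates, C V^-1 (y - X beta) with
the appropriate cross-covariance C per component; the identity
beta + a0 + a1 c + t0 + t1 c = y holds exactly and is tested.

## Interaction tests, meta-analysis, multiplicity

Five likelihood-ratio comparisons: OVERALL (full vs null, 4 df),
GXE_UNADJ (GxE-only vs null, 2 df), RXE_UNADJ (RxE-only vs null, 2 df),
GXE_ORTHOGONAL (full vs RxE-only, 2 df), RXE_ORTHOGONAL (full vs GxE-only,
2 df); chi2 = max(0, 2 dlogL) against the upper chi-square tail. The
orthogonal tests correct for the collinearity between the GxE kernel
(K o cc') and the RxE diagonal (c^2), which both inflate variance with |c|.

Large cohorts are split into near-equal random groups fitted independently;
per-split p-values are combined by Fisher's method (-2 sum ln p ~
chi2(2k)) and estimates by fixed-effect inverse-variance weighting. Splits
whose fits fail to converge are dropped from the combination and logged.
Grid scans over traits x covariates use a Bonferroni threshold
alpha/(n_traits x n_covariates) on the meta-analyzed p-value of each test
type. A cell is declared significant only if it additionally passes the
legitimacy rule: the FULL fit's s2_a1 + s2_t1 must be nonnegative
(boundary inclusive), screening out estimates outside the legitimate
parameter space that unconstrained REML can produce.

## Risk prediction and trajectories

From the FULL fit, the expected phenotype is yhat_i = a0_i + (a1_i + t1_i)
c_i. Individuals are ranked by estimated total interaction effect a1 + t1
(or a single component for the GxE-only / RxE-only variants) and labeled
BOTTOM20 / MIDDLE20 / TOP20 — the extreme quintiles plus the same-size band
centered on the median; quantile ties break by a stable sort on position so
labels are deterministic. Each stratum splits into prospective cases and
controls (case status is an input; the package never derives diagnosis from
phenotypes), a line of yhat on c is fitted per cell, and intercepts/slopes
are aggregated across analyses with a paired case-minus-control t-test per
stratum (pairing within analysis and stratum). Before aggregation across
trait/covariate pairs, values are sign-oriented so that "unfavorable"
points the same way everywhere: variables measured in a
higher-is-healthier direction (HDL, physical-activity measures, healthy
diet) are negated; a pair in which both names flip cancels.

## Heritability comparison

h^2 = s2_a0 / (s2_a0 + s2_t0) under both the additive (GREML) and full
(MRNM) fits — intercept components only, i.e. the genetic share of variance
at the covariate mean, assuming environmental homogeneity. The ratio of
change (h2_MRNM - h2_GREML)/h2_GREML quantifies still-missing heritability:
when genuine interaction variance exists, the additive fit absorbs it into
the residual and deflates h^2, so the expected ratio is positive. Ratios
are averaged per trait across analyses with a normal-approximation 95% CI
(mean +/- 1.96 SE). A variance-at-c profile is available as a diagnostic
but never feeds the headline ratio.

## Synthetic data

The generator emulates a biobank-style design at desk scale:

* genotypes: m biallelic SNPs, allele frequency p_j ~ U(maf range, default
  0.05-0.5), dosages Binomial(2, p_j); no linkage disequilibrium.
* covariate: standard normal by default, or ordinal with equiprobable
  levels (mimicking categorical lifestyle variables); ordinal codes are
  standardized exactly like continuous values.
* phenotype: y = sum_j w_ij (a_j + b_j c_i) + fixed effects + e0_i + e1_i
  c_i with column-standardized dosages w, per-SNP effect pairs (a_j, b_j) ~
  N(0, G/m) — the 1/m scaling matches the GRM normalization so total
  genetic variance is G-controlled regardless of m — and residual pairs
  from T. The generating per-individual values (truth record) are kept for
  recovery tests, stored alongside the observables in one bundle.
* case status: liability = sqrt(h2_liab) x standardized true risk
  (g0 + (g1+e1)c) + independent normal noise, thresholded at the empirical
  (1 - prevalence) quantile, so the realized case count is exact. Defaults:
  prevalence 0.05, liability h^2 0.5.

Defaults plant s2_a0 = 0.4, s2_a1 = 0.2, s2_t0 = 0.3, s2_t1 = 0.1 (unit
total variance at c = 0, moderate interactions). What the generator does
*not* emulate: LD structure, imputation dosage uncertainty, genotype-
covariate correlation (a heritable-covariate switch is deliberately absent;
the bivariate treatment of the covariate as a second trait is out of
scope), population stratification beyond what random genotypes produce, and
assortative structure. Passing tests therefore demonstrate correctness of
the estimation and testing machinery under the model's own assumptions, not
robustness to those real-data complications.

## Problem sizes used in validation

All validation sizes are package choices balancing statistical resolution
against a single-CPU budget; each property was sized so that it is expected
to hold with margin under the stated effect sizes.

* Parameter recovery: 15 replicates at n = 1000, m = 1000; per-replicate
  sampling SD of each component is ~0.05, so the mean of 15 pins bias well
  inside +/-0.05.
* Optimizer-vs-brute-force: n = 40, m = 120 toys; constrained space (see
  above), iterated 5-point grid over 9 shrinking rounds with coordinate
  polish as the independent certificate.
* Test calibration: 100 null replicates at n = 500, m = 600 (the
  chi-square asymptotics of the variance-component LRT are comfortably
  accurate from n ~ 500; at n ~ 300 they are visibly anti-conservative);
  orthogonality: 50 replicates at n = 800 with s2_t1 = 0.3 planted, where
  the orthogonal RxE test's power is near 1 and the orthogonal GxE test's
  size stays nominal.
* Heritability change: 25 replicates each (planted s2_t1 = 0.3 / null) at
  n = 500, m = 500.
* Trajectories: 30 analyses at n = 600, m = 500, prevalence 0.1, liability
  h^2 0.5.

## Numerical and design choices

* HWE is tested by a 1-df chi-square on observed vs expected genotype
  counts (not the exact test) — appropriate in the large-n regime and
  directly oracle-checkable. SNPs failing MAF < 0.01, HWE p < 1e-4, call
  rate < 95%, or duplicated ids are excluded, in that reporting order.
* Missing dosages are mean-imputed (per-SNP 2p) before standardization;
  allele frequencies are computed in-sample after QC.
* Relatedness pruning is greedy over pairs in descending relatedness with a
  seeded random choice of which member to drop; a threshold of 0.05 is the
  default but assumes enough SNPs that GRM noise (~1/sqrt(m)) sits well
  below it — desk-scale analyses should raise it accordingly. Samples
  beyond +/-6 SD on PC1/PC2 of the GRM are removed after pruning.
* The inverse normal transform uses the Blom offset 3/8 (configurable);
  ties share average ranks. Sample (n-1) SDs are used throughout.
* The middle stratification band is centered on the median (configurable to
  quantile bands).
* Bonferroni is applied per grid to the meta-analyzed p-values of each test
  type; outputs carry raw and corrected calls so alternative multiplicity
  conventions remain comparable.
* Every output table carries a hash of the run configuration; re-running
  with the same config and seed reproduces all numeric outputs.

## Limitations

Dense O(n^3)-per-iteration algebra limits single fits to a few thousand
individuals per split — the intended regime (the sample-splitting +
meta-analysis design exists precisely to cap per-fit n). No multi-trait
(bivariate) fitting, no multiple GRMs, no sparse/low-rank approximations,
no FDR alternatives, no liability-scale heritability conversion. The AI
sampling covariance (inverse AI at the optimum) is unreliable for
parameters whose estimates sit on the positive-definiteness boundary; the
gradient-norm diagnostic flags such fits.
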