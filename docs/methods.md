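# Methods

`gxeset` implements set-based (gene-based) tests for gene–environment
interaction (G×E) on common-variant genotype data, together with the
simulation machinery used to validate them. This note records the models,
the numerical choices, and the limits of what the test suite demonstrates.

## Single-SNP substrate

Every test starts from the per-SNP generalized linear model

    g[E(Y)] = β0 + βG·G_l + βE·E + βGE·G_l·E + βX'·X,   l = 1..L,

with identity link for continuous traits and logit link for binary traits;
G_l is the minor-allele count (0, 1, 2), E the exposure, X confounder
covariates. The interaction MLE β̂GE and its variance V̂ come from the
observed information; Wald inference uses the standard normal reference
(two-sided), which is indistinguishable from the t reference at the sample
sizes these scans target (10³–10⁴ subjects) and reproduces published
single-marker p-values from their printed (β̂, se) pairs.

Before any gene-based test, a continuous trait is standardized to mean 0 and
standard deviation 1 (n−1 denominator) and the exposure is affinely scaled to
[0, 1] (binary exposures pass through as {0, 1}). Scaling puts G·E on the
same 0–2 range as G, so a single interaction-effect prior is meaningful for
any exposure; standardization is applied uniformly across tests because all
implemented statistics are scale-equivariant, and one common scale keeps
cross-test comparisons interpretable.

Fitting is batched: the L per-SNP designs of a window are stacked into one
tensor and solved with a single einsum/solve pass (closed-form weighted least
squares for gaussian, IRLS with tolerance 1e−8 on the coefficient change and
a 100-iteration cap for binomial). Runaway coefficients (|β| > 10³,
indicating separation) and singular designs are flagged non-converged and
excluded downstream rather than silently dropped. The batched core is
cross-checked against statsmodels OLS/GLM fits in the test suite.

## ADABF: adaptive combination of Bayes factors

For each SNP the evidence for interaction is Wakefield's approximate Bayes
factor under a N(0, W) prior on βGE,

    BF = sqrt(V̂ / (V̂ + W)) · exp(β̂² W / (2 V̂ (V̂ + W))),

with W = 0.2² = 0.04 by default — the prior that 95% of interaction effects
lie within ±0.4 (odds ratios within [0.67, 1.49] for binary traits). The L
BFs are sorted descending and partially summed, S_k = Σ_{l≤k} log BF_(l);
the test adapts over k = 1..L, so a gene with one strong interacting SNP and
many nulls is not diluted.

Calibration is by resampling under the global null. Interaction-estimate
vectors are drawn from MVN(0, Σ), where Σ_ll = V̂_l and Σ_ll′ =
r_ll′·sqrt(V̂_l V̂_l′) with r_ll′ the sample correlation of the interaction
covariates G_l·E and G_l′·E after residualizing each on its own nuisance
design [1, G_l, E, X]. This is the asymptotic covariance of the marginal
Wald estimates under the null: it reduces exactly to [[V̂]] for one SNP and
carries the window's linkage disequilibrium off the diagonal. For binary
traits the residualization and correlation are weighted by the working
weights μ̂(1−μ̂) of a null logistic fit of Y on [1, E, X], the IRLS analogue
of the gaussian construction. Σ is symmetrized and any negative eigenvalue
clipped at zero (logged when the smallest eigenvalue is below −1e−8·trace).

Each resampled vector is converted to BFs (using the same W and diagonal
variances), sorted, and cumulated into null S rows. The per-k p-value of any
row is its ≥-rank within the stack of the observed row plus the B null rows,
divided by B+1, and the gene p-value is the fraction of rows whose minimum
per-k p-value is at most the observed row's. Because the observed row counts
itself, p ≥ 1/(B+1) > 0, and the construction is exactly exchangeable under
the null — finite-B valid without nested resampling, at O(B·L log B) cost.
BF ties are broken by ascending SNP index (stable sort); the MVN factor's
eigenvector signs are canonicalized (largest-magnitude component positive),
which makes the resampling stream — and hence the p-value — invariant to SNP
column order under a fixed seed.

Resampling is sequential: start at B = 10³, multiply by 10 while the running
p-value is ≤ 100/B, stop at B = 10⁷. Draws accumulate across stages, so a
sequential run and a fixed-ceiling run agree within Monte-Carlo error. The
genome-wide scan derives per-gene seeds as CRC32(base_seed, gene_id), so
serial and parallel executions produce identical reports.

## SBERIA: two-stage weighted burden test

Stage 1 screens each SNP with a statistic asymptotically independent of the
interaction test: the SNP main effect on the trait (default, and the right
choice when the exposure is randomized), or the SNP–exposure association
(logistic fit, for binary exposures in case-control designs where
ascertainment induces G–E correlation). A SNP whose filter p-value is below
0.10 receives weight +1 or −1 (the filter estimate's sign); otherwise the
weight is 0.0001. Both constants are exposed as configuration.

Stage 2 fits one GLM with all L main effects, E, the covariates and the
scalar burden covariate E·(G'ŵ), and Wald-tests the burden coefficient
(1 df). The Wald flavor is a choice of convenience; a likelihood-ratio test
is indistinguishable at these sample sizes. If the main-effect block is
rank-deficient (duplicated SNPs, L ≥ n) it is ridge-stabilized with a
penalty of 1e−6·trace(D'D)/p on the G columns only. No MAF-based variant
weighting is applied.

The empirical independence of the two stages (near-zero correlation between
the stage-1 minimum p and the stage-2 p over null replicates) is asserted in
the test suite, since it is the property that makes the data reuse valid.

## Variance-component score test

The interaction coefficients are treated as random effects with variance τ₂
in g[E(Y)] = δ0 + δG'G + δE·E + δGE'S + δX'X, S = [E·G_1 … E·G_L], and
H0: δGE = 0 reduces to H0: τ₂ = 0. The score statistic is the kernel
quadratic form Q = ‖S'(Y − μ̂0)‖² at the null fit. Its null distribution is
a mixture of 1-df chi-squares with weights the eigenvalues of

    M = scale · [S'WS − 2·B·C0·B' + B·C0·(D'WD)·C0·B'],

where D is the null design, W the working weights, B = S'WD, C0 =
(D'WD + P)⁻¹ with P the (possibly zero) ridge penalty, and scale = σ̂²
(gaussian) or 1 (binomial). Unpenalized, M collapses to the familiar
projection S'(W − WD(D'WD)⁻¹D'W)S. Interaction effects are treated as
independent (no exchangeable-correlation search).

Two small-sample details matter at desk scale. For gaussian traits σ̂² uses
the n−p denominator. For binary traits the fitted μ̂(1−μ̂) systematically
under-estimates the residual variance when many main effects are fitted
(expected shrinkage ≈ 1−h_i, the GLM leverage; with L = 20 main effects at
n = 1000 this is a ~2% deflation of M that visibly inflates the type-I error
to ~0.055 at nominal 0.05). The implementation therefore divides the working
weights by (1−h_i), clipped at 0.5, when building M — the binomial analogue
of the gaussian degrees-of-freedom correction, in the spirit of HC2
covariance adjustments. With it, 20,000-replicate null studies at n = 1000
are calibrated at both 0.05 and 0.01.

Mixture tail probabilities use Liu's four-moment match by default; Imhof's
numerical inversion of the characteristic function is available as
`method="imhof"` (absolute accuracy ~1e−4, limited by the oscillatory
integral for small L). Main effects under the null are fixed (`"fixed"`) or
ridge-penalized (`"ridge"`) with λ chosen by generalized cross-validation
over a 25-point log grid spanning [1e−4, 1e4]·n on the weighted working
regression; a GCV failure falls back to λ = 1e−4·n with a warning. The
exact criterion and grid of existing ridge-based implementations are not
published, so parity is asserted at the level of calibration, not
value-for-value.

## Genotype handling and QC

Genotypes are minor-allele count matrices; any SNP whose stored frequency
exceeds 0.5 is reflected (g → 2−g, allele labels swapped) on construction,
and SNPs are kept sorted by (chromosome, position), 1-based inclusive
coordinates throughout. QC removes, in order: SNPs with call rate strictly
below 95% (a SNP at exactly 95% is retained), SNPs with a 1-df chi-square
Hardy–Weinberg goodness-of-fit p below 5.7e−7 (the chi-square test is
adequate at the target sample sizes; an exact test would matter only for
rare variants), and monomorphic SNPs (every downstream regression is
degenerate for them). Cryptic relatedness is pruned on user-supplied pairwise
PI-HAT = Pr(IBD=2) + 0.5·Pr(IBD=1) scores: pairs above 0.1 are resolved
greedily by removing the sample with the most remaining flagged pairs, ties
broken toward the lexicographically later id (deterministic). IBD
probabilities are consumed, not estimated.

Gene windows extend annotated gene bounds by 50 kb on both sides (clamped at
position 1), the conventional allowance for flanking regulatory sequence;
SNP assignment is inclusive at both bounds. Missing genotypes inside a
tested window are mean-imputed per SNP, keeping the sample size constant
across the SNPs of one gene. Samples missing the trait, exposure or any
covariate are dropped with a logged count. Gene-level significance is
flagged at p < 2.5e−6 (0.05/20,000 genes, Bonferroni) and suggestive at
p < 5e−5; single-SNP results at p < 5e−8. All thresholds are strict
inequalities.

## Simulation framework

The genotype generator emulates an LD-structured common-variant window: two
haplotypes per sample are drawn from an AR(1) Gaussian copula (default
ρ = 0.5) and thresholded at each SNP's normal MAF quantile, MAF ~ Uniform
(default [0.05, 0.5]). This reproduces the features the tests are sensitive
to — a MAF spectrum, Hardy–Weinberg genotype frequencies, and decaying
pairwise LD — but not features of real genomes such as recombination
hotspots, long-range LD, rare variants or genotyping error, so passing
calibration here demonstrates correctness of the statistics under realistic
correlation, not robustness to every artifact of real array data.

Phenotypes follow the standard G×E simulation design: E ~ Bernoulli(0.5);
continuous Y = Σ βG_l·G_l + Σ βGE_l·G_l·E + e with e ~ N(0, 1); binary Y
from logit P(Y=1) = −0.4 + (same linear term), the intercept log(0.4/0.6)
giving baseline prevalence 0.4. Eleven scenarios combine d = 1 or 4
interacting SNPs with sign patterns of main and interaction effects (the
"4-4" and "4-8" patterns — half the main effects opposing the interactions —
are the ones that defeat signed burden weighting). Effect magnitudes are
uniform on [0.08, 0.12] / [0.13, 0.17] / [0.18, 0.22] for continuous traits
and [log 1.05, log 1.15] / [log 1.25, log 1.35] / [log 1.45, log 1.55]
(log-odds) for binary traits. The d causal SNPs default to evenly spaced
interior columns (i·L div (d+1), i = 1..d), so they sit in LD with flanking
null SNPs; an explicit index list can override this.

### Problem sizes

The package's own validation studies run at desk scale, chosen so the whole
suite completes on one CPU: null calibration uses n = 1000 subjects, L = 20
SNPs and 5000 replicates per trait family, with the empirical rates compared
inside 95% binomial bands; power orderings use 300–500 replicates at a
relaxed α = 0.001. The sequential-resampling ceiling in these studies is
B = 10⁵ rather than the production default 10⁷: rejection decisions at
nominal 0.05/0.01 (or 0.001) only require p-values resolved to ~10⁻³, where
the early-stopping rule makes the two ceilings coincide; the 10⁷ default is
kept for genome-wide scans, whose significance threshold (2.5e−6) genuinely
needs it. Single-SNP interaction effects (d = 1) at these sample sizes give
near-zero power at α = 0.001, so the d = 1 power comparisons are only
informative at more liberal α.

## Known limitations

- The ADABF null covariance is the asymptotic Wald covariance with
  (weighted) residualized-covariate correlations; it is an approximation
  whose adequacy is demonstrated empirically by calibration, exact only in
  the single-SNP case.
- The random-main-effect and joint (main + interaction) variants of the VC
  test, and the exchangeable-ρ search over interaction effects, are not
  implemented; nor is the polygenic (genome-wide pruning) variant of ADABF.
- Principal components are accepted as covariates but never computed;
  likewise PI-HAT scores are consumed, not estimated from genotypes.
- `--threads` is accepted by the CLI but the scan currently executes
  serially; per-gene seeding already guarantees that a future parallel
  implementation reproduces serial results.
- Binary-exposure scaling assumes {0, 1} coding; survival and count traits
  are out of scope.
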