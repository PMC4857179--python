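# Methods

## The problem

Score-based Bayesian-network structure learning assumes independent,
identically distributed sample units: the likelihood of a candidate DAG
factorizes into per-node regressions and each node's parents are chosen by
comparing nested models with BIC, AIC, or a likelihood-ratio test (LRT).
Family-based and longitudinal studies violate the independence assumption —
relatives share genetic background, repeated measures share a subject — and
naive per-node tests treat correlated rows as independent evidence, which
inflates false-positive edge rates and yields over-connected networks.

`mebn` augments every node model with a vector of correlated random
effects and scores structures with the *integrated* likelihood, in which
those random effects are marginalized out.  Under global parameter
independence the augmented likelihood still factorizes over nodes, so the
K2-style modular search survives unchanged; only each node's local
likelihood and its penalty change.

## Node models

**Gaussian nodes.**  With parents collected in a design matrix `X`
(intercept included),

    y = X beta + alpha + e,   alpha ~ N(0, gamma^2 A),   e ~ N(0, sigma^2 I),

so `V(y|X) = gamma^2 A + sigma^2 I`.  The structure matrix `A` is fixed and
known: the additive genetic relationship matrix `2K` for family data (block
diagonal by family, entries `2 k_ij`), a block of ones per subject for
exchangeable repeated measures (then the within-subject correlation equals
the heritability-like ratio `h^2 = gamma^2/(gamma^2 + sigma^2)`), or an
AR(1) correlation block.  The integrated likelihood is the multivariate
normal density and is evaluated per family after rotating by the
eigenvectors of each `A` block; rotated observations are independent with
variances `sigma^2 + gamma^2 s_i`.  Maximum likelihood reduces to a 1-D
bounded search over `h^2 in [0, 1)` (Brent, tolerance 1e-8) with the total
variance profiled in closed form; `beta` is the GLS solution.  ML rather
than REML is used throughout because the search compares models with
different fixed effects, for which REML likelihoods are not comparable.

Because the eigen-rotation depends only on `A`, it is computed once per
dataset.  `GaussianMixedScorer` additionally groups rotated rows by
eigenvalue and stores per-group Gram matrices of the *full* candidate
design, so every sub-model fit during a forward search costs a few small
matrix operations regardless of `n`.  A forward search over 10 candidates on
n = 4656 takes milliseconds.

**Survival nodes.**  The hazard is `lambda_0(t) exp(X beta + R)` with a
log-normal frailty `R ~ N(0, gamma^2 A)` on the log-hazard scale.  For
fixed `gamma^2` the penalized Breslow partial likelihood is maximized
jointly in `(beta, R)` by Newton–Raphson (the curvature in the linear
predictor is assembled in O(n^2) from cumulative risk-set sums), and the
integrated partial likelihood is approximated by Laplace's method:

    l_M(gamma^2) = l_pen(beta_hat, R_hat) - 1/2 log det(I + gamma^2 A H),

with `H` the partial-likelihood curvature at the mode.  An outer bounded
Brent search maximizes `l_M` over `log gamma^2` on `gamma^2 in [1e-6, 10]`
(tolerance 1e-4 for single fits; the simulation harness relaxes the outer
tolerance to 2e-3, which changes `l_M` only at second order but roughly
halves the cost of the thousands of fits a study needs).  Newton iterations
warm-start from the previous outer evaluation.  At `gamma^2 -> 0` the fit
reproduces the ordinary Cox partial likelihood, which is also the naive
comparator.  Ties use Breslow's approximation; simulated continuous times
make ties measure-zero.  The Laplace approximation was preferred over
quadrature because kinship couples all members of a family: the frailty
integral does not factorize into low-dimensional pieces.  Adaptive
tensor-product Gauss–Hermite quadrature over small exchangeable clusters
serves as the accuracy oracle in the test suite (agreement within 0.1 on
the log scale).

## Selection metrics

Nine metrics, all "lower/smaller is better" or "p below alpha":

| label | likelihood | rule | sample size in penalty |
|---|---|---|---|
| BIC_M | integrated | score improvement | n (events `d` for survival) |
| BIC_J | integrated | score improvement | Jones: `n_e = 1' C^{-1} 1` |
| BIC_Y | integrated | score improvement | Yang-type: `n_e = sum_f n_f^2 / (1' C_f 1)` |
| BIC_C | integrated | score improvement | number of clusters |
| AIC_M | integrated | score improvement | — |
| LRT_M | integrated | p < alpha | — |
| BIC_F | IID | score improvement | n (events for survival) |
| AIC_F | IID | score improvement | — |
| LRT_F | IID | p < alpha | — |

`C` is the correlation matrix implied by `gamma^2 A + sigma^2 I`, computed
per family block; blocks use the heritability fitted on the node's
intercept-only model, recomputed per node.  Jones' quadratic form and the
family-sum form coincide on exchangeable blocks (`m / (1 + (m-1) rho)`) and
satisfy `n_clusters <= n_e(Yang) <= n_e(Jones) <= n` in general
(Cauchy–Schwarz), which yields the documented liberality ordering of the
BIC chain.  On the synthetic 8-member family template the two corrections
are numerically close (2555 vs 2483 at `h^2 = 0.5`), so BIC_J and BIC_Y
behave near-identically here; larger, more inter-related real pedigrees
separate them further.  LRT p-values refer `2 (l_full - l_reduced)` to a
chi-square with df equal to the difference in fixed-effect counts; variance
components are re-estimated under both hypotheses and not counted (the
variance parameter space is common to both).

## Forward search and error accounting

For each node, starting from the empty parent set, every remaining
candidate is fitted and tested at each level; all candidates passing the
criterion are *flagged*, the best flagged candidate (smallest p or score,
earlier column on ties) joins the parent set, and the search stops at the
first level with no flag.  Every candidate evaluation is one test; in null
studies every flag is a false positive.  The false positive rate is total
flags over total tests, and the family-wise error rate is the fraction of
replicates with at least one flag.  Counting *all* flagged candidates (not
just the selected one) is what makes per-level counts exceed the replicate
count for liberal metrics, and it carries near-significant candidates into
deeper levels, where they are counted again if still flagged.

Orderings are enumerated exhaustively with declared root nodes first and
sinks last (survival nodes are implicit sinks: a censored pair cannot act
as a regressor); the number of free nodes is capped (default 8).  Learned
networks are ranked by the raw global integrated log-likelihood, the sum of
node log-likelihoods, as a crude Bayes-factor surrogate.  A consequence
worth knowing: orderings incompatible with a sparse true DAG produce
Markov-equivalent *denser* structures whose raw likelihood is equal or
higher, so the top-ranked network over all orderings is generically a dense
representative of the equivalence class.  Recovery of a specific sparse
structure is therefore assessed along the generating ordering.  Application
mode supports a per-node Bonferroni correction: alpha divided by the node's
level-1 candidate count, held fixed across levels.

## Synthetic cohorts and simulation design

The study cohort mimics a family study of 582 families and n = 4656: each
family contributes 8 sampled members — two full siblings (their parents
unsampled), each with an unrelated spouse and two children — giving
relationship values `2k in {1, 0.5, 0.25, 0.125, 0}` within a family.
Gaussian traits are drawn exactly through the spectral decomposition of
`V = gamma^2 A + sigma^2 I`; the error variance is fixed at
`sigma^2 = 1` and the genetic variance takes `gamma^2 in {1/3, 1, 3}`,
i.e. `h^2 in {0.25, 0.5, 0.75}`.  Null covariates are 10 SNPs gene-dropped
down the pedigree (founder frequencies uniform on (0.05, 0.5), Mendelian
transmission, columns redrawn until the sample minor-allele frequency is at
least 5%), so candidate predictors carry the same familial correlation as
real genotypes.  Survival traits invert a Weibull(2, 2) baseline through
the proportional-hazards relation with frailty `R ~ N(0, gamma^2 A)`;
censoring times are Uniform(0, 10), calibrated once to about 20% censoring
under the null and kept fixed.

True-effect covariates for power studies are three standard normals with a
common pairwise correlation, independent of family structure.  Their
coefficients define the effect tiers: the weak/moderate/strong tier is
calibrated so that the marginal (single-covariate) detection power at
alpha = 0.005 on the default cohort is about 0.3/0.6/0.9 — Gaussian tiers
0.046/0.060/0.080, survival tiers 0.063/0.079/0.106 (larger because the
frailty attenuates marginal hazard ratios; the survival calibration uses
the ordinary Cox LRT, which is equivalent for family-independent
covariates).  Published power *values* are not reproduction targets — the
source tables do not print their effect sizes — only the direction of the
matched-alpha comparison between the integrated LRT and the BIC variants.

Per-replicate randomness comes from counter-based seed streams
(`SeedSequence(entropy=seed, spawn_key=(rep,))`), so studies are
reproducible and order-independent.  Within a replicate all metrics analyze
the same data and share fit caches: integrated-likelihood metrics share one
cache, naive metrics another.

**What the generator does not emulate.**  Real family studies have variable
family sizes and deeper relationship structure; real genotypes carry
linkage disequilibrium and allele-frequency spectra that gene dropping from
uniform founder frequencies does not reproduce; the censoring mechanism of
any particular study is unknown.  Passing tests therefore demonstrate
calibration and correct relative behavior of the metrics under a faithful
*class* of correlated designs, not agreement with any specific cohort
beyond the tolerances used.

## Problem sizes

The continuous null study runs its published size: 582 families, 1000
replicates (about two minutes thanks to the cached rotations).  The
survival null study runs at a reduced size chosen as a sensible desk-scale
design — 40 families (n = 320) and 120 replicates — because each
Cox-frailty fit requires dense n x n curvature factorizations; false
positive *rates* are per-test quantities and transfer across cohort size,
which the wider tolerance on the survival comparisons reflects.  The
five-variable network study uses 581 family clusters with unit genetic and
error variance per node in the correlated regime.

## Numerical choices and degenerate inputs

- Heritability search on `[0, 1 - 1e-6]`; the `gamma^2 = 0` boundary is
  explicitly compared and allowed (null variance component).
- Rank-deficient candidate designs raise immediately (Cholesky of the
  normal equations); inside a forward search a failing candidate is skipped
  with a warning and logged.
- Exact linear fits (`sigma^2 = 0`) are flagged degenerate rather than
  scored.
- Singular structure blocks (e.g. a shared frailty's block of ones) receive
  a 1e-8 ridge before inversion; the Laplace log-determinant is formed so
  that the ridge directions cancel.
- Negative LRT statistics beyond optimizer tolerance raise a diagnostic
  error instead of silently clipping.  The tolerance is scaled to the
  likelihood's accuracy: essentially round-off for exact Gaussian
  likelihoods, but 0.01 for survival nodes, because the Laplace
  approximation is non-monotone in fixed-effect nesting at the ~1e-3 level
  (the curvature correction moves with the mode).  Frailty fits also
  re-evaluate the integrated likelihood at the variance optima of cached
  nested sub-models and keep the best, which bounds that artifact.
- Ties among equal-scoring candidates break toward the earlier column, for
  determinism.

## Known limitations

- Categorical nodes are not supported; the integrated likelihood here is
  exact only for Gaussian nodes and Laplace-approximate for survival nodes.
- One variance component per node: no simultaneous kinship plus
  repeated-measures effects, no heteroscedastic errors.
- The AR(1) correlation parameter is profiled on a grid with local
  refinement in single fits; forward searches fix it at the null-model
  estimate per node.
- Frailty fits hold dense curvature matrices: practical up to a few
  thousand subjects, not tens of thousands.
- Exhaustive ordering enumeration is factorial in the number of free nodes;
  the cap forces explicit orderings or more root/sink constraints beyond 8
  free nodes.
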