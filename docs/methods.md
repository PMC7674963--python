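# Methods

## The model

`rrtdm` implements single-trait random regression test-day models for
first-lactation daily milk yield. A record of cow *i* at days in milk
(DIM) *t* is modeled as

    y_itklm = HYS_l + AGE_m + DIM_t + Σ_{k=0}^{nr} z_tk a_ik
            + Σ_{k=0}^{np} z_tk pe_ik + e_itklm

* **HYS** — herd × calving-year × calving-season contemporary group.
  Calving seasons are 1 = {Mar–May, Sep, Oct}, 2 = {Jun–Aug},
  3 = {Nov–Feb}; the year is the calving year, because seasons are defined
  on calving months.
* **AGE** — calving age in months, classes 20–23, 24–27, 28–31, ≥32.
* **DIM** — one fixed level per day, 301 levels over DIM 5–305 (only
  observed levels receive an equation).
* **z_tk** — orthonormal Legendre polynomials
  `LP_k(x) = sqrt((2k+1)/2) P_k(x)` evaluated at the standardized DIM
  `x = 2(t−5)/300 − 1`. Orders 0–5 are unit-tested against the explicit
  monomial forms; higher orders work through the recurrence.
* **a_i ~ N(0, A ⊗ G)** — genetic regression coefficients, with A the
  pedigree numerator relationship matrix; **pe_i ~ N(0, I ⊗ P)** — the
  cow's permanent-environment coefficients (recorded cows only).
* **e** — residual with variance v (homogeneous) or v_i in ten 30-day DIM
  classes (5–34 … 275–305), handled as weights w_i = v̄/v_i on the residual
  precision.

Derived quantities: daily variances σ²_g(t) = z_t'Gz_t and
σ²_pe(t) = z_t'Pz_t; h²(t) and repeatability as the genetic and animal
shares of daily phenotypic variance; EBV305 = Σ_t z_t'a = u'a with u the
basis column sums; 305-day h² from the variance of the 305-day sum
(u'Gu, u'Pu, Σ_t σ²_e(t) with daily residuals independent — the standard
aggregated-yield heritability, which sits above the mid-lactation daily
h² because the independent residuals largely average out of the sum).
Whole-lactation repeatability is deliberately *not* defined on the sum:
there it degenerates to ~1 for any parameters; `rep_305` is instead the
trajectory-average variance ratio, whose values line up with reported
whole-lactation repeatabilities.

## Identifiability of fixed effects

With full indicator sets, HYS + AGE + DIM are confounded twice over (the
AGE and DIM blocks each sum to the all-ones vector spanned by HYS). The
last observed AGE level and the last observed DIM level are
zero-constrained (columns dropped); reported fixed-effect estimates list
the constrained levels as 0. Estimable contrasts, variance components and
EBVs are unaffected by this choice. BIC's sample size uses
n = records − rank(X) with the rank computed numerically from the
unconstrained indicator matrix.

## REML

The restricted likelihood is evaluated through Henderson's mixed-model
equations: with C the (constrained) coefficient matrix,

    −2 logL = (n−r) log 2π + log|C| + log|R| + (nr+1)·log|A| + q·log|G|
            + n_cow·log|P| + y'Py,

where log|A| = Σ log d_i comes free from the pedigree (d_i the Mendelian
sampling variance share) and y'Py = y'R⁻¹y − rhs'·solution.

Two algorithms are provided.

* **direct** (default): the residual scale is profiled out analytically
  (v̂ = y'P₀y/(n−r)); the ratio matrices G/v and P/v are parameterized by
  their Cholesky factors (log-diagonal), which enforces positive
  definiteness without constraints; L-BFGS-B with finite-difference
  gradients maximizes the profiled likelihood. Each evaluation is one
  numeric sparse factorization: the coefficient-matrix pattern and a
  symmetric minimum-degree ordering are computed once per dataset, after
  which a factorization at ~17,000 equations costs ≈0.15 s. This direct
  maximization was chosen over EM/AI acceleration at scale because exact EM
  and AI updates need selected elements of C⁻¹ (a sparse selected inverse),
  which the available sparse linear algebra does not provide; dense
  inverses are infeasible beyond a few thousand equations.
* **em**: classical EM-REML with exact trace terms from the dense C⁻¹,
  monotone in the restricted likelihood. Guarded to ≤8,000 equations; used
  as an independent cross-check (the two algorithms agree on shared data)
  and for the ascent property test.

Convergence: relative function tolerance ~1e-9 (option `tol`, default
1e-6, scaled internally), maximum 200 iterations; results carry the
iteration count, a convergence flag, and the −2 logL path. Iterates whose
G/v or P/v ratio matrix is catastrophically ill-conditioned (smallest
eigenvalue below 1e-10 of the largest) are rejected outright: near the
singular boundary the quadratic form y'Py loses all precision and can
fake arbitrarily good likelihoods, so such points are treated as
infeasible rather than trusted. Log-diagonals of the Cholesky factors are
clamped to ±30 so wild line-search steps cannot overflow. Positive
definiteness in EM is maintained by eigenvalue flooring at 1e-8 × trace.
Nested-order model scans warm-start each order from the previous order's
estimates padded with a small diagonal; this speeds convergence and makes
the nested −2 logL ordering hold by construction of the start.

## Heterogeneous residual variances

The ten class variances are not free parameters of one joint
maximization; they are obtained by the weighting scheme: fit a weighted
REML at current weights, re-estimate class variances from the fitted
residuals as v_i = SS_i/(n_i − d_i), rescale so that
mean(v_i) = v̂·mean(1/w) (the internal consistency identity of the
weights), recompute w_i = v̄/v_i, and repeat until the v_i stabilize
(default: max relative change < 1%, at most 8 passes).

The degrees-of-freedom share d_i is the class's sum of hat-matrix
leverages, tr_i(W C⁻¹ W′R̃⁻¹), estimated by Hutchinson probing on the
cached factorization with a fixed probe seed (so the fit stays
deterministic). This matters: the Legendre covariates peak at the
lactation edges, so random-effect shrinkage removes far more apparent
residual variance from the first and last DIM classes than a proportional
allocation suggests — with a fixed-effects-only d_i the edge-class
variances come out 20–30% low and the weights correspondingly distorted.
When no factorization is available, a cheaper fallback charges each class
for the DIM fixed-effect levels it owns plus a proportional share of the
remaining fixed-effect degrees of freedom. Class variances are clamped to
v̄/20…20v̄ so a nearly empty DIM class cannot blow up the weighted fit.

## Synthetic data

The generator draws from the model's own generative process, at a scale a
desk machine can analyze:

* **Pedigree**: discrete generations, random mating, no selection; 40 base
  sires + 335 base dams, two generations of 2 daughters/dam plus 40 young
  sires per generation (~3,200 animals). Every non-founder female is
  recorded (~2,010 cows), so dam–daughter pairs both carry records, as in a
  multi-year recording scheme with overlapping cohorts; each generation
  calves in its own block of the six calving years (2010–2015) across 8
  herds.
* **Genetic coefficients** by Mendelian-sampling recursion
  (founders N(0,G); descendants midparent + N(0, d_i G)) — the exact
  A ⊗ G covariance, inbreeding included.
* **Records**: ~6–10 tests per cow at ~30-day intervals starting at DIM
  5–35; y = mean curve + HYS + AGE + z'a + z'pe + e; yields outside
  5–80 kg are truncated out (≤2% under defaults). A data-extraction
  cutoff (90 days after the end of the last calving year, configurable or
  disableable) removes tests that would postdate the extract, so recently
  calved cows have partial lactations — as in any real data pull, and a
  prerequisite for order effects to show in predictive validation, since
  a 305-day EBV for a partially recorded cow extrapolates the curve.
* **Anchors**: the mean lactation curve is a monotone-cubic interpolation
  of published DIM-class means of first-lactation Holstein daily yield
  (peak ≈26.6 kg near day 50, declining to ≈21 kg); the default
  heterogeneous residual profile is the published order-3 DIM-class
  residual-variance column (elevated early lactation, mean 12.2 kg²); the
  default G and P are diagonal-dominant with a mild negative
  intercept–slope covariance, scaled so daily h² ≈ 0.25 mid-lactation
  (0.15–0.35 across DIM) and repeatability ≈ 0.7 (up to ~0.86 on the last
  days, where the reference residual profile is smallest). The truth file
  stores G, P, v_i and every animal's true EBV305 computed with the same
  basis code the estimator uses.

What the generator does **not** emulate: selection and culling, seasonal
reproduction biology, multiple lactations, herd-size heterogeneity,
recording gaps correlated with yield. Passing tests therefore demonstrate
correctness of the machinery and statistical behavior under the model's
own assumptions, not robustness to the ways real data violate them.

## Study problem sizes

The replicated studies in the test suite and acceptance script use scales
chosen to keep a full run on one CPU within minutes while preserving the
statistical structure: parameter recovery uses the default ~2,010-cow,
~16,000-record datasets (order-2 truth, homogeneous-matched residuals;
20 replicates in the test suite, 8 in the acceptance script); the
predictive-ability comparison uses ~720-cow datasets with an order-3
truth whose higher-order genetic variance is substantial, so that an
underfit order-1 model visibly loses predictive ability at this scale
(10 replicates in the test suite, 6 in the script; REML fits
iteration-capped at 40/15 L-BFGS iterations for orders 1/3, which moves
the full-vs-reduced correlations by under 0.03 while tripling throughput);
the nested-likelihood scan and unit tests use a few hundred cows, and the
null-case weight calibration ~1,800 cows so each DIM class carries ~2,000
records. Reduced-data breeding values in the validation reuse the
full-data variance components (a common shortcut in validation studies;
re-estimation is available via `refit_reduced`).

## Known limitations

* REML sampling error at the default simulation scale is substantial: the
  smaller diagonal elements of G and P carry 15–25% relative sampling SD
  and h²(305) about ±0.04, with the optimizer verified to sit at the exact
  restricted-likelihood optimum (identical results from different starts
  and tolerances, EM agreement on smaller data). Recovering every diagonal
  element to 20% reliably needs an order of magnitude more cows — which is
  why real studies of this design use populations of 50,000+ cows.
* Unknown-parent groups are not implemented; unknown parents are treated
  as base-population draws. Genomic relationships, multiple traits and
  lactations, and persistency indices are out of scope.
* The heterogeneous-residual parameter count in AIC/BIC counts all ten
  class variances (nR = 10); treating the weights as known (nR = 1) is
  available via the scoring options.
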