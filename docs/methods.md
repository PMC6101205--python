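# Methods

## Model

`rrglm` fits multivariate generalized linear models in which the
conditional law of a response vector Y given predictors X = x belongs to
a k-parameter canonical exponential family,

    f(y | x) = exp{ eta_x' T(y) - psi(eta_x) } h(y),

and the natural parameter depends linearly on the predictors.  The
natural parameter splits into a covariate-dependent block of dimension
k1 and a covariate-free block of dimension k2 (empty for the multinomial
and Poisson families; the spherical-variance parameter for the Gaussian
family with unknown variance):

    eta_x = ( eta_bar1 + beta1 x1 + beta2 x2 ,  eta_bar2 ).

Here x1 holds r designated predictors whose k1 x r coefficient block
beta1 is constrained to have rank at most d, while beta2 (k1 x (p - r))
and the intercepts are unrestricted.  With d = min(k1, r) the model is
the ordinary full-rank multivariate GLM.  Stacking
xi = (eta_bar1, vec beta1, vec beta2, eta_bar2) with column-stacking
vec, the map x -> eta_x is xi-linear with design operator
F(x) = blockdiag((1, x') ⊗ I_k1, I_k2), which is how all fitting code
evaluates the model.

A note on the multinomial cumulant: for q categories with the last as
reference and T(y) the indicator vector of the first q - 1 categories,
the log-normalizer is psi(eta) = log(1 + sum_i exp(eta_i)).  Some
presentations print the normalizer without the logarithm; only the log
form makes the mass function sum to one, and that is what is
implemented (with a max-shift log-sum-exp so large |eta| arising during
optimization cannot overflow).

## Estimation

*Full-rank MLE.*  Fisher scoring on the average log-likelihood
L_n(xi) = (1/n) sum_i [eta_i' T(y_i) - psi(eta_i)], with the expected
information (1/n) sum_i F(x_i)' hess_psi(eta_i) F(x_i), which is positive
definite whenever the design has full column rank.  Step-halving
enforces a monotone likelihood trace.  Convergence requires both a small
mean score (sup-norm at most 1e-9, well inside the 1e-6 contract) and a
small Newton step: under data separation the score vanishes while the
step stays large, and requiring both lets the fitter report separation
as explicit non-convergence instead of returning a spurious optimum.

*Rank-restricted MLE.*  The restricted model is parametrized through the
factorization beta1 = C B (C: k1 x d, B: d x r), and the likelihood is
maximized by alternating two closed sub-problems: with B fixed, the
model is an ordinary GLM in the reduced predictors nu = B x1 joined with
x2; with C fixed, it is still linear in (eta_bar1, B, beta2, eta_bar2)
with per-observation design [I | x1' ⊗ C | x2' ⊗ I].  Each half-step is
a complete Fisher-scoring solve, so the outer trace is nondecreasing.
Initialization takes the full-rank MLE and truncates the SVD of its
beta1 block.  After every sweep the factors are renormalized to the
corner form C = [I_d; A] (rows permuted so the leading d rows of beta1
are independent), which pins the chart without moving the identified
product C B.  The outer loop stops when the relative likelihood change
falls below 1e-9 (at most 500 sweeps).

Because the alternation converges only linearly, a terminal Gauss-Newton
polish runs on the injective corner chart (eta_bar1, A, B, beta2,
eta_bar2): its gradient has full column rank, so the projected-score
Newton step converges quadratically and delivers estimates at
near-machine accuracy.  This is what lets the Gaussian special case
reproduce the closed-form truncated-SVD solution to 1e-6 and the
vacuous restriction d = min(k1, r) reproduce the full-rank MLE
essentially exactly.

Only the product beta1 = C B is identified; C and B separately are not
(the map (C, B) -> (C M, M^{-1} B) changes nothing).  All reported
estimates, comparisons and standard errors concern identified
quantities: entries of xi, including every entry of beta1.

Degenerate inputs are rejected up front: empty response categories,
constant rank-constrained predictors, rank-deficient designs, and sample
sizes below the parameter count all raise informative errors before any
iteration.

## Asymptotic covariance

The unrestricted MLE satisfies sqrt(n)(xi_hat - xi0) -> N(0, W) with
W = (E[F(X)' hess_psi(F(X) xi0) F(X)])^{-1}; the plug-in estimate
replaces the expectation by the average over the observed x_i and xi0 by
xi_hat (predictors are treated as random, jointly distributed with the
response).  The restricted MLE is asymptotically normal with covariance

    avar = Pi(W^{-1}) W = G (G' W^{-1} G)^+ G',

where G is the Jacobian of (eta_bar1, vec C, vec B, vec beta2,
eta_bar2) -> xi, whose vec(beta1) block is [B' ⊗ I_k1 | I_r ⊗ C], and
Pi(S) = G (G' S G)^+ G' S is the oblique projection onto span(G),
self-adjoint under the inner product induced by S.  G is rank-deficient
by exactly the d^2 factor redundancy, so the pseudoinverse is used; the
projection depends on G only through its column span, which makes the
choice of generalized inverse (and of the factorization C B) immaterial.
The test suite verifies this span-only dependence against the injective
corner-chart gradient, where an ordinary inverse is valid.  Because Pi
is a projection, W - avar is positive semidefinite: the rank restriction
can only sharpen inference.

Per-coordinate standard errors are sqrt(avar_ii / n) — the
per-observation scale on which coefficient tables are conventionally
reported.  Wald z-tests, p-values and confidence intervals are entrywise
and unadjusted for multiplicity (tables flag 5% significance with a
star); a case-resampling bootstrap (resampling (x_i, y_i) pairs jointly,
consistent with random predictors) provides an alternative covariance
estimate on the same sqrt(n) scale.

*Rank selection.*  For each candidate rank, AIC = -2 loglik + 2 m uses
the effective parameter count m = k1 + k1 d + d r - d^2 + k1 (p - r) + k2,
i.e. raw factor entries minus the d^2 reparametrization redundancy —
the dimension of the rank-d matrix manifold plus the free blocks.  A
caveat on its error rate: when the truth has rank exactly d, the closure
of the rank-(d+1) manifold has a cone singularity there, so the
likelihood-ratio statistic between adjacent ranks is stochastically
larger than a chi-square with the naive degrees of freedom, and AIC
overfits the rank somewhat more often than standard nested-model
heuristics suggest.  In the packaged rank-1 study design the test suite
and acceptance script measure a rank-1 selection rate around 90%, with
essentially all errors choosing rank 2.

## Synthetic data

The generator draws predictors i.i.d. from per-column laws (Bernoulli or
normal) and responses from the family at eta_x.  The packaged
`workforce_like_scenario` emulates a marital-status questionnaire study:
a 4-category multinomial response (reference: married/partnered), twelve
binary lifestyle/psychology indicators forming the rank-constrained
block with a rank-1 coefficient matrix, and two unconstrained continuous
covariates (age centered at 30 with SD 10 years; a log-education score,
mean 1.4, SD 0.5).  The model has 45 free parameters unrestricted and 24
under the rank-1 restriction.

Generator defaults, chosen once:

* Rank-1 structure beta1 = C B with C = (1, 1.38, 1.96)' (corner form;
  the third log-odds contrast reacts about twice as strongly as the
  first) and loadings B spread over the 0.0-1.1 log-odds range, one of
  them ("worry") exactly zero so the battery contains a true null
  coordinate for size checks.  Signal strengths were set, using the
  analytic covariance at the true parameters, so that the identified
  product C B is recovered to within 10% relative Frobenius error at
  n = 8000.
* Unconstrained effects of the order seen in such studies: age
  (-0.19, 0.012, 0.086) per year, log-education (0.34, -0.37, -0.09).
* Binary prevalences 0.20-0.45 and intercepts
  eta_bar1 = (-3.92, -3.64, -6.48), solved so the marginal category
  distribution is about (0.20, 0.10, 0.05, 0.65): the reference category
  dominates, and the rarest (widower-like) category still averages ~100
  observations at n = 2000, keeping the third contrast informative.

What the generator does *not* emulate: dependence among the binary items
(real questionnaire items are positively correlated), missing data,
survey weighting, and any deviation from the fitted model family.
Passing tests therefore demonstrate correctness of the estimator and its
asymptotics *under the model*, not robustness to misspecification.

## Numerical choices

* Scoring: step-halving (at most 40 halvings) with a 1e-13 slack for
  float comparisons; domain violations (e.g. a nonnegative Gaussian
  variance natural parameter) also trigger halving.
* Outer alternation: relative log-likelihood tolerance 1e-9, max 500
  sweeps; corner renormalization each sweep; renormalization is skipped
  (and retried next sweep) if the current product is numerically rank
  deficient.
* Corner factorization: the identity permutation is kept whenever the
  leading d rows are already independent; otherwise rows are pivoted by
  QR with column pivoting on beta1'.
* Pseudoinverses: `numpy.linalg.pinv(..., hermitian=True)` on the
  projected information; W is inverted through its eigendecomposition,
  raising an error naming the null direction if the information is
  singular.
* Ties in AIC rank selection resolve to the smallest rank (pandas
  `idxmin` keeps the first minimizer).

## Monte-Carlo problem sizes

The test suite checks distributional claims at the sizes at which they
are stated: 500 replicates at n = 2000 for the sampling-covariance
comparison, 1000 replicates at n = 2000 for 95% CI coverage (pooled over
the 36 entries of beta1) and for the size of the null-coordinate Wald
test, and 100 replicates at n = 4000 for AIC rank recovery.  The
acceptance script (`scripts/acceptance.py`) recomputes the same
quantities at moderately reduced sizes — 500 replicates at n = 2000
shared between the covariance, coverage and size checks, 50 replicates
for AIC — which keeps a full from-scratch rerun within a few minutes on
one CPU while leaving Monte-Carlo error well inside the margins of
interest.

## Known limitations

* Only canonical links are supported; no offsets, weights, or dispersion
  estimation beyond the Gaussian natural-parameter treatment.
* No penalized or nuclear-norm estimation: p must be small relative to n
  (the fitter refuses n below the parameter count).
* The covariance formula assumes the model is correctly specified; the
  general misspecification-robust sandwich is not implemented.
* Formal rank tests are out of scope; rank selection is by AIC only.
* Separation is detected and reported, not resolved (no penalization).
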