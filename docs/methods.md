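# Methods

## Models

All generators are built on the Rasch item response function
P(X=1|θ,β) = logistic(θ − β) with abilities θ ~ N(0,1) and difficulties
β ~ N(0,1) unless stated otherwise. Within a simulation condition the item
parameters are drawn once and held fixed; abilities (and any latent class
membership) are redrawn for every replication. The violation families:

- **surface_ld** — Rasch data with β₁ = −0.626 (prerequisite) and
  β₂ = 0.184 (dependent) forced into the first two positions; after
  generation, persons with the (X₂=1, X₁=0) pattern have X₁ overwritten to
  1 with probability 0.9 (major violation) or 0.8 (minor). At these
  settings the dependent item is solved by ≈46% of persons and the
  surviving violation pattern occurs in ≈1.3% / 2.6% of rows, which the
  acceptance script re-measures at N = 10⁶.
- **multidim** — two traits, bivariate standard normal with correlation
  r ∈ {0.3, 0.7}; the first half of the items loads on trait 1, the second
  half on trait 2 (the assignment is arbitrary under exchangeable
  difficulties, so the fixed split costs no generality). Requires an even
  item count. θ₂ is constructed as r·z₁ + √(1−r²)·z₂, so r = 1 degenerates
  exactly to the unidimensional model.
- **mixed_rasch** — each person independently belongs to a latent class
  with probability 0.40; for class members the difficulties of the first
  20% or 40% of items are shifted by −0.8. Membership is i.i.d. Bernoulli
  rather than an exact quota: "40% of respondents" with latent classes is
  most naturally a population proportion, and the binomial wobble is part
  of the sampling variability being studied. Class indicators are redrawn
  with the persons each replication.
- **twopl** — discriminations α drawn once per condition from a log-normal
  with log-mean 0 and log-variance 0.09 or 0.25 (sd of log α = 0.3 or
  0.5). Fixing α per condition parallels the handling of the difficulties;
  the alternative (redrawing per replication) would mix conditions of
  varying severity into one cell.
- **guessing** — constant lower asymptote γ ∈ {0.1, 0.25}:
  P = γ + (1−γ)·logistic(θ − β), mimicking random success among ten or
  four response options.

What the generators deliberately do not emulate: missing responses,
polytomous items, speededness, response styles, and ability distributions
other than the normal. Passing tests therefore certify behavior under
clean, normally-distributed-ability data; empirical datasets can misfit in
ways outside this family.

## Conditional maximum likelihood and the LR test

The conditional likelihood given raw scores depends on the difficulties
only through elementary symmetric functions (ESFs) of the easiness values
ε_i = exp(−β_i). ESFs and their item-deleted first derivatives are
computed with the summation recursion — O(n²), no subtractions — which is
stable for the test lengths used here (n ≤ 50). The negative
log-likelihood is minimized by damped Newton: the Hessian is the
score-group-weighted conditional covariance of the response vector, whose
pair-deleted ESFs are obtained by downdating the item-deleted table
(forward recursion for ε ≤ 1, backward for ε > 1, so rounding errors are
damped in both regimes; the Hessian only steers the step, the objective
and gradient are always evaluated from the stable recursion). The flat
all-ones direction is ridge-penalized, keeping iterates centered;
convergence requires gradient max-norm < 1e-8 within 100 iterations, with
step-halving that accepts on a likelihood decrease or — near the optimum,
where likelihood differences sink below float rounding — on a gradient
decrease. Estimates are reported under the sum-zero constraint. Persons
with raw score 0 or n are excluded (conditional likelihood 1) but counted
in the fit report.

The LR test splits persons at the median raw score computed after
removing extreme scores; persons at the median go to the high group, the
same convention T10 uses, so both tests share one split operation. Items
constant within any group are removed from **all** fits (total and both
groups) so the group parameter spaces stay nested inside the total one,
and df = n′ − 1 on the surviving item set; dropped items are recorded in
the result diagnostics. p-values come from the upper χ² tail only, since
LR is a one-sided misfit measure.

## Margin-fixed sampling and the nonparametric tests

The null reference set for T10/T11 is the collection of 0/1 matrices with
the observed margins. The sampler is the simplest chain with the required
uniform stationary law: propose two rows and two columns uniformly; flip
the 2×2 submatrix iff it is a checkerboard. The proposal is symmetric and
every proposal is accepted when valid, so no Metropolis correction is
needed. Defaults scale with the matrix mass m (number of ones): burn-in
100·m proposals, thinning 2·m proposals between retained draws — declared
choices, validated by the uniformity tests on enumerable margin sets
rather than matched to any existing package's settings. The inner loop is
numba-compiled; index streams are pre-drawn from the single numpy
Generator so one seed governs everything.

Because row sums are conserved, the median split derived from any sampled
matrix equals the observed one; the implementation computes it once and
asserts this. T11's null correlation matrix ρ is the element-wise mean of
the phi-correlation matrices of the same B draws used for the reference
distribution (no second independent sample), matching the statistic's
two-step definition; reusing the draws induces slight conservatism, which
is accepted. p-values use the add-one convention
p = (1 + #{T_b ≥ T_obs}) / (B + 1), so p ∈ (0, 1] always. B defaults to
500 for single-dataset testing and 300 inside simulation grids.

## Marginal maximum likelihood and M2

The MML fit fixes slopes at 1 and the ability mean at 0, and frees the n
difficulties plus the latent standard deviation (q = n + 1 parameters) —
the parameterization that gives df = 27 for an 8-item test
(s = 36 moments). Integration uses 61 Gauss–Hermite nodes, far more than
needed for moment accuracy at the studied sample sizes. The EM algorithm
iterates posterior node weights (E) and an inner Newton solve for (β, σ)
to the inner optimum (M), making the marginal log-likelihood provably
non-decreasing; convergence is a maximum parameter change below 1e-5
within 500 cycles.

M2 compares the s = n + n(n−1)/2 observed first- and second-order moments
with their model-implied values. The weight matrix is assembled from
model-implied moments up to order four evaluated at the fit (standard
asymptotic practice; third/fourth-order moments come from the same
quadrature by local independence given θ). The quadratic form is computed
on an orthonormal basis of the null space of the moment Jacobian's
transpose — algebraically identical to the textbook
C = Ξ⁻¹ − Ξ⁻¹Δ(Δ′Ξ⁻¹Δ)⁻¹Δ′Ξ⁻¹ form, which is retained as an independent
cross-check route in the tests, but avoids inverting the full s × s
covariance. Degrees of freedom are s − q. Dense algebra is used
throughout; at n = 50 (s = 1275) the matrices are still desk-scale.

## Simulation harness

Seeding is hierarchical (condition seed → item-parameter stream + one
stream per replication), making tables byte-reproducible and independent
of execution order; the replication stream also feeds the bootstrap
sampler, so a single integer reproduces any cell. Replications where a
test raises (degenerate data such as a score group with no usable items,
or non-convergence) are excluded from that test's denominator and
reported as a failure count — exclusion avoids imputing non-rejections,
and the count keeps the choice auditable. Rates are reported with the
binomial Monte-Carlo standard error √(p(1−p)/reps).

Default problem sizes: 500 replications per condition (1000 for the null
calibration checks), bootstrap B = 300 inside grids — large enough that
the three-standard-error bands used in the acceptance checks are a few
percentage points wide, small enough for single-CPU runs.

## Known limitations

- No missing-data handling; matrices must be complete and binary.
- The nonparametric tests are not feasible for very large matrices, since
  chain length scales with the number of ones.
- The M2 implementation covers the Rasch parameterization only (unit
  slopes, free variance), not 2PL/bifactor variants, and only the
  order-2 member of the statistic family.
- Score splits are two-group median splits; covariate-based or multi-group
  splits are not exercised.
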