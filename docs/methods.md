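# Methods

## Model and power formulas

Both designs are analysed under a linear mixed model with a random cluster
intercept. For a parallel-group (PG) cluster trial, the outcome of
participant *i* in cluster *j* is

    Y_ij = mu_C + X_j mu + c_j + e_ij,

with c_j ~ N(0, sigma_c^2), e_ij ~ N(0, sigma_e^2), and X_j the arm
indicator. For a cross-sectional stepped wedge (SW), a fixed period effect
is added and the treatment indicator becomes the cluster-period entry
X_jk of the roll-out matrix. The intra-cluster correlation is
rho = sigma_c^2 / (sigma_c^2 + sigma_e^2) = sigma_c^2 / sigma^2.

Testing H0: mu <= 0 with Z = mu_hat / sqrt(Var(mu_hat)) at one-sided level
alpha gives power Phi(delta / sqrt(Var) - z_{1-alpha}) at target difference
delta. The variances are closed forms:

* PG with 1:1 allocation: `Var = 4 {1 + (n-1) rho} sigma^2 / (C n)`.
* SW (Hussey–Hughes):
  `Var = C sigma^2 (1-rho) [1 + rho(nT-1)] / ( n { [1 + rho(nT-1)](CU - W) + n rho (U^2 - CV) } )`,
  where U is the number of treated cluster-periods, W the sum of squared
  column sums and V the sum of squared row sums of the treatment matrix.

Every closed form is cross-checked in the test suite against a generalized
least-squares oracle that assembles the cluster(-period)-mean information
matrix from the model covariance (sigma_e^2/n on the diagonal, sigma_c^2
shared within cluster) and inverts it; agreement is required to relative
1e-8 over random configurations.

The z-based (Normal reference) test is used throughout, with no
small-sample t or Satterthwaite correction; reported powers are therefore
mildly optimistic for very small cluster counts. Two-sided testing is
expressed by halving alpha.

## Degenerate designs

A standard wedge with T = 2 has a single simultaneous switch, so the
treatment indicator is collinear with the period effect: the variance
formula's denominator is zero and `var_sw` raises rather than returning a
number. At rho = 1 the SW variance tends to 0 (the (1 - rho) factor); the
implementation returns variance 0 and power 1 by continuity, so that
quadrature nodes arbitrarily close to 1 are handled without special-casing
by the caller. Odd cluster counts are accepted when building a PG design
(with a warning) but rejected by the variance formula unless explicitly
forced, because the closed form assumes exactly equal arms.

When T - 1 does not divide C, remainder clusters are assigned one per step
starting from the earliest step, keeping total cluster count exact while
staying as close as possible to the equal wedge; a warning marks the
unequal wedge. Cluster-period sizes may be fractional: the variance is a
continuous function of n, and the design-comparison grid requires
n = N / T with non-integer values.

## Priors and "correct specification"

Design-stage priors quantify uncertainty in rho and sigma; they are never
updated (the analysis stays frequentist). Implemented families: truncated
Normal TN(0, 1, m, s^2) on [0, 1] and Beta(a, b) for the ICC; Gamma(k,
rate theta) for the SD; and a point mass that degenerates the framework to
the ordinary frequentist calculation. The Gamma is parametrized by rate —
its density is proportional to sigma^(k-1) e^(-theta sigma) — and the
constructor takes the rate as an explicitly named argument to avoid the
shape/scale ambiguity. Truncated-Normal moments use the standard
formulas (mean m + s (phi(l) - phi(u)) / (Phi(u) - Phi(l)), and the
matching variance expression); these are validated in tests against direct
numerical integration of the density, which is treated as the source of
truth.

A prior is "correctly specified" when its mode equals the point estimate a
conventional calculation would plug in. `match_mode` constructs such
priors from a (mode, sd) pair: Gamma in closed form via a quadratic in
sqrt(k); Beta by parametrizing a = 1 + mode·t, b = 1 + (1-mode)·t (which
fixes the mode for every t > 0) and solving t against the SD; truncated
Normal by fixing m = mode (valid while the untruncated mode is interior)
and root-finding the scale. Requested SDs outside the family's reachable
range (both [0,1] families flatten towards the uniform, SD 1/sqrt(12))
raise an error that states the feasible range.

The stepped-wedge SD prior stored in the `ogrady` fixture is Gamma(17.32,
rate 40), kept verbatim from the source material even though its mode
(0.408) is slightly below the trial's point estimate sigma = 0.426; the
discrepancy is documented rather than "fixed", since re-deriving the
parameters would change the fixture's published values.

## Expected power

Expected power is the prior-weighted average of the frequentist power,
over the ICC alone (SD fixed) or jointly over ICC and SD (independent
priors). Integrals are computed by quantile-transform Gauss–Legendre
quadrature: with Q the prior's inverse CDF, the ICC integral becomes
int_0^1 P(..., Q(v)) dv, and the joint case a tensor product over the unit
square. The transform concentrates nodes where the prior has mass, handles
Beta shapes below 1 (density unbounded at an endpoint) because no node
maps to the endpoint, and needs no truncation of the Gamma's support.

Defaults: 129 nodes per dimension, refined by doubling until two
successive estimates agree within 1e-6 (the reported `est_error` is that
difference); failure to converge by ~4000 nodes raises with diagnostics.
A Monte-Carlo estimator over joint prior draws (seeded, with standard
error) serves as an independent stochastic oracle; quadrature and Monte
Carlo are required to agree within max(3 MC standard errors, 1e-3) on
randomized specifications.

Two empirical regularities worth noting, both visible in the test suite:

* EP is monotone non-decreasing in C and tends to 1 as C grows for any
  proper priors with delta > 0 — this underwrites the sample-size search.
* Adding SD uncertainty *lowers* EP relative to the ICC-only calculation
  wherever the design is adequately powered (the prior weighs in
  low-power, large-sigma scenarios), but the inequality reverses in the
  deeply under-powered regime (small C), where power is locally convex in
  sigma and spreading mass raises the average. Tests assert the inequality
  from the motivating trial's cluster count upward.

## Sample-size search

The smallest admissible design meeting power >= 1 - beta (frequentist) or
EP >= 1 - gamma (hybrid; gamma defaults to beta) is found by geometric
doubling to bracket, then bisection on the admissible lattice: steps of 2
for PG (exact 1:1 allocation) and T - 1 for the standard wedge (equal
steps), with an `allow_unequal` escape hatch enabling step 1 plus the
remainder rule. Counts always round up; minimality is asserted by checking
that one step fewer fails. Searching over the cluster size n at fixed C
detects the PG power asymptote — power is bounded by
Phi(delta sqrt(C / (4 rho sigma^2)) - z) as n grows — and reports the
bound instead of looping.

## Design comparison on a common budget

The PG-vs-SW comparison fixes a common number of measurements per cluster
N (n = N for PG, n = N/T per period for SW), a standardized effect
delta/sigma and one-sided alpha, and maps expected power under a
TN(0, 1, m, s^2) ICC prior over a grid of (m, s). Since the SD prior is a
point mass here, EP depends on (delta, sigma) only through delta/sigma
(asserted to 1e-10), so the grid is computed at sigma = 1. The default
replication grid spans m in [0, 0.5], s in (0, 0.5] at resolution 0.005;
CI-oriented tests use 0.025. The equal-EP contour is extracted by bilinear
cell interpolation (contourpy); an empty contour means one design
dominates the whole grid. The PG-favourable region summary reports the
largest m and s with EP_PG > EP_SW, with the grid resolution as the
implied uncertainty.

Finding: the PG-favourable region is lower-left connected to within the
contour's own width, but the equal-EP boundary wiggles slightly (order
0.005 in EP) near m ≈ 0.1 at small s, so strict cell-wise monotonicity
fails exactly on the contour. Tests therefore assert connectivity only for
cells clearly (> 0.01 in EP) on either side.

## Problem sizes used in the checks

Randomized verification uses designs up to ~30 clusters and 8 periods
(GLS oracle), 100k Monte-Carlo draws per EP check, and comparison grids at
resolution 0.005 (101 x 100 cells) for replication-scale runs and 0.025
for the broader property checks — sizes at which every check completes in
seconds while leaving the quadrature and search machinery fully exercised.

## Known limitations

* Normal-reference testing only; no degrees-of-freedom corrections.
* Cross-sectional stepped wedges with a single random cluster intercept;
  no closed cohorts, decaying correlations, transition periods or
  incomplete wedges.
* Equal cluster sizes; no attrition inflation.
* No priors on the effect size (assurance proper) and no posterior
  updating.
* The comparison module treats only ICC-prior uncertainty; both-prior
  comparisons are out of scope.
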