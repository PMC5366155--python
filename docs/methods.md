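# Methods

## Model

The observed beta-value matrix `D` (m CpGs × n samples, entries in [0, 1])
is modeled as `D = T A + E`: `T` (m × k) holds k latent methylation
component (LMC) profiles constrained to the unit box, `A` (k × n) holds
per-sample mixture proportions constrained column-wise to the probability
simplex, and `E` is measurement noise.  An LMC is a prototype methylome —
usually a cell type, but any recurrent source of methylome variation
(age-related drift, genotype, batch) can surface as a component.

Estimation minimizes

    f(T, A) = ‖D − TA‖²_F + λ Σ_{i,s} T_is (1 − T_is)

subject to the box and simplex constraints.  The penalty ω(x) = x(1 − x)
is symmetric around 1/2 and vanishes at 0 and 1.  Its role is
identifiability: on data consisting only of mixtures, the unpenalized
problem admits a continuum of solutions (any simplex whose hull covers the
data cloud fits equally well), and unpenalized estimates collapse onto the
most extreme observed mixtures.  Since single-cell methylation is
essentially binary, pushing profile entries towards {0, 1} selects the
biologically plausible solution among the least-squares-equivalent ones.
For λ large enough the minimizing profiles are exactly binary.

A baseline mode replaces the equality constraint with `Σ_s A_sj ≤ 1`
(column sums at most one) and sets λ = 0, reproducing the behavior of
unregularized reference-free deconvolution tools; its proportion columns
are not interpretable as complete mixing fractions.

## Optimization

Minimization alternates two subproblems:

* **Proportions (`opt_A`).**  For fixed `T`, each sample column decouples
  into a simplex-constrained least-squares problem.  It is solved exactly
  by enumerating active sets: for each subset of components allowed to be
  nonzero, the equality-constrained KKT system is solved (shared across
  all columns, so the enumeration is vectorized), and the best feasible
  candidate is the global minimizer of the convex program.  The
  sub-simplex variant adds a slack component with an all-zero profile.
* **Profiles (`opt_T`).**  For fixed `A`, rows of `T` decouple, but the
  penalty is concave in `T`, making each row a difference-of-convex
  program.  The concave part −λ Σ T² is linearized at the current iterate
  (concave–convex procedure), yielding the convex surrogate
  `‖D − TA‖²_F + λ Σ (1 − 2 T̂_is) T_is`, whose exact minimization over the
  box never increases the true objective.  Each surrogate is a box-
  constrained quadratic program with a Hessian (`A Aᵀ`) shared by all
  rows; it is solved exactly by enumerating the 3^k lower/upper/free
  activity patterns, again vectorized across rows with per-pattern
  factorizations precomputed once per CCP loop.

Pattern enumeration is exact and deterministic but exponential in k; it is
capped at k ≤ 12 (proportions) and k ≤ 8 (profiles), which covers the
method's intended regime of single-digit component counts.  Ties between
multiple minimizers (possible for degenerate inputs such as duplicated
profile columns) are broken by enumeration order; degenerate linear
systems fall back to pseudo-inverse/least-squares solves.  Constant CpG
rows receive no special casing — the constraints keep the row problems
well posed.

The outer loop records the objective after every A/T cycle; the trace is
non-increasing because both updates are descent steps.  Convergence is
declared when the relative objective change drops below `rel_tol`
(default 1e-8) or after `max_outer_iter` (default 100) cycles; the CCP
inner loop uses the same relative rule with `max_ccp_iter` (default 50).
Non-convergence is reported on the result, not raised.  After
optimization, profiles are clipped to [0, 1] and proportion columns
renormalized when their sums deviate by less than 1e-6; larger violations
raise.  A single integer seed drives all random initializations (profiles
uniform on [0, 1], proportion columns flat-Dirichlet — the initialization
law is a package choice); runs are bitwise reproducible, and the
row-decoupled subproblems give results independent of evaluation order.
The penalty sum is used unnormalized (not rescaled by m), so comparable λ
values on datasets of different size require rescaling by the user; this
is deliberate and documented rather than hidden.

## Model selection

`k` and `λ` are selected by column-leave-out cross-validation: samples are
partitioned into `n_folds` folds (default 10, seeded shuffle, sizes
differing by at most one); each training subset is factorized as usual;
held-out columns are then fit against the trained profiles by plain
simplex-constrained least squares (the penalty does not enter the held-out
fit, and the equality constraint is always used there since proportions
are the quantity of interest); the held-out squared error, averaged per
matrix entry for comparability across splits, is the CVE.

Because the problem is non-convex, each grid cell is fit from `n_restarts`
random initializations (default 50) and the best in-sample objective wins.
λ is searched on a coarse grid (default {0, 1e-5, 1e-4, 1e-3, 1e-2,
1e-1}), then on a finer log-spaced grid spanning the two coarse points
bracketing the coarse argmin (when the argmin sits at the λ = 0 edge, the
fine grid spans two decades below the upper bracket, and the zero cell is
kept for comparison).  Solutions at nearby λ grid points are similar, so
each cell is additionally warm-started from the profile solutions of up to
`neighbor_window` (default 5) preceding grid points in an ascending pass,
followed by a descending refinement pass offering each cell its following
neighbors' solutions.  Fold-level fits reuse the *full-data* solutions of
the cell and its neighbors as warm starts rather than per-fold solutions,
bounding memory; this is a deliberate simplification of a literal
per-fold smoothing scheme.  Per-cell seeds are derived deterministically
from (seed, k, λ-index), so grid cells can be evaluated in any order with
identical results.

The CVE decreases with k through the true component count and then
flattens (further components fit noise that does not generalize to
held-out columns).  `select_model` automates the resulting visual
"elbow" rule: it returns the smallest k whose best-over-λ CVE is within
`flat_tolerance` (default 1%, relative) of the global grid minimum,
with that k's argmin λ.  The full CVE table is always emitted so users
can override the automated choice with prior knowledge.

## Interpretation

**Matching.**  Estimated components are compared to reference profiles on
their shared probe IDs (exact string match) via the k × k* matrix `S` of
column-wise Pearson correlations.  By default both matrices are centered
first (each column minus its matrix's per-row mean across columns), which
in practice sharpens matches by removing the shared average methylome;
centering is switchable.  Component ī matches reference j̄ when S[ī, j̄]
maximizes column j̄; the match is unambiguous when it also maximizes row ī.
The score ε = (#unambiguous matches) / min(k, k*) lies in [0, 1] and is 1
exactly when a perfect mutual-maximum bipartite matching exists.
Zero-variance columns have undefined correlations and are excluded with a
warning; argmax ties break towards the lowest index and are flagged.

**Clustering.**  Estimated and reference profiles are concatenated on
shared probes and clustered agglomeratively with average linkage on the
distance 1 − r.  The signed distance (not 1 − |r|) is used because the
direction of methylation matters: an anti-correlated profile is not a
near-duplicate.

**Component-specific CpGs.**  A CpG is specific to component i when its
methylation there differs from the *mean* of the other components by more
than θ (default 0.33).  An alternative reading compares against the *sum*
of the other components; it is dimensionally awkward for k > 2 (the sum
scales with k while θ ∈ (0, 1)) but available behind `literal_sum=True`
for comparability.  A pairwise variant thresholds |T_li − T_lj| directly.
Sets for different components may overlap.

**Reference-based proportions ("regression").**  Given reference profiles,
proportions are estimated by the same exact simplex-constrained
least-squares solver used inside the factorization, restricted to shared
probes.

**Preselection.**  `select_most_variable` ranks CpGs by across-sample
variance (ties by probe ID, survivors keep row order);
`select_discriminative_cpgs` ranks by one-way ANOVA F across labeled
groups (for marker selection on purified samples).

## Simulation framework

The generator emulates mixtures of purified cell-type methylomes without
requiring any external data:

* **Profiles**: entries drawn from a two-spike mixture — probability 0.4
  each of a near-zero Beta(1, 30) draw or its mirror near one, uniform
  otherwise — matching the strongly bimodal distribution of real
  cell-type methylomes.  A configurable fraction of rows (default 0.2) is
  discriminative: all components share one value except one randomly
  chosen component, whose value is flipped to 1 − x.  Non-discriminative
  rows are identical across components, so the discriminative fraction
  directly controls the deconvolution signal.
* **Proportions**: columns i.i.d. Dirichlet(v·α) with simplex base α
  (default uniform) and concentration scale v — v = 1 highly variable,
  v = 10 moderately, v = 100 marginally variable across samples.
* **Noise**: i.i.d. Gaussian with sd 0.05 / 0.1 / 0.2 for low / moderate /
  high noise tiers; the composed matrix is clipped to [0, 1] because
  downstream code validates the beta range (the unclipped matrix is kept
  on the dataset as `D_raw`).
* **Effects**: for case/control studies, either a methylation shift —
  m_e CpGs sampled without replacement, each shifted in component l by a
  Normal(δ, σ) draw with probability 1/2 (an independent per-CpG fair
  coin), clipped — or a proportion shift replacing the Dirichlet
  concentration α_l in the case group only.

Presets named `two-distant`, `two-similar`, `three`, `five` mirror common
blood cell-type constellations by varying k and the discriminative
fraction (the "similar" pair shares all but 5% of rows).

What the simulations do **not** emulate: probe-level Infinium chemistry
(type I/II bias, beta-value heteroskedasticity), spatial CpG correlation,
population structure in the profiles, or missing values.  Passing
recovery tests on these simulations therefore demonstrates correctness of
the optimization and selection machinery under the model's own
assumptions, not robustness to array artifacts.

## EWAS adjustment

The association module fits, per CpG, `phenotype ~ methylation (+ extra
covariates)` — logistic for binary phenotypes, OLS for numeric — and
reports the Wald test of the methylation coefficient.  Technical and
demographic covariates can instead be removed beforehand by per-CpG OLS
residualization (the two-stage scheme); both orderings are exposed since
either may be preferred in practice.  When a complete set of simplex
proportions is supplied as covariates, the last one is dropped (the
columns sum to one and would be collinear with the intercept).  With
large k, only the k′ components with the largest average proportions need
be included (`top_k_lmcs`).  Per-CpG non-convergence (e.g. quasi-perfect
separation) yields a missing p-value and a warning count, not a failure;
the logistic iteration cap is 100.  No multiple-testing correction is
applied by default because the module's diagnostic target is the p-value
distribution itself: `qq_inflation` pairs sorted observed −log10 p with
uniform order-statistic expectations and summarizes inflation as
λ_gc = median observed χ²(1) quantile / null median — λ_gc ≈ 1 for a
calibrated null, ≫ 1 under composition confounding.

## Benchmark studies and problem sizes

Three end-to-end studies (in `methdecon.benchmarks`) are used by the test
suite and the acceptance script; their sizes are chosen to run in minutes
on one core while exercising the regimes of interest:

* regularization study: m = 500, n = 30, k = 3, v = 10, noise 0.05,
  discriminative fraction 0.5, λ grid {0, 1e-4, 1e-3, 1e-2, 1e-1},
  10 restarts, 10 folds; CV fits capped at 50 outer iterations with
  relative tolerance 1e-6 (the CVE ranking is insensitive to the final
  creep of a fully converged fit);
* recovery study: m = 2000, n = 60, k = 3, v = 10, noise 0.05, 3
  restarts, 5 folds, 40 outer iterations, with a CVE-vs-k trace at
  k ∈ {2, 3, 4};
* confounding study: m = 400, n = 200, k = 3, one concentration
  parameter tripled in cases, no CpG-level effect; adjustment uses the
  true simulated proportions, isolating the diagnostic from estimation
  error.

## Known limitations

* Exact pattern-enumeration solvers limit k (8 for profile updates); very
  large k would need an iterative QP solver and would leave the regime
  where binary-prototype deconvolution is statistically sensible anyway.
* Alternating minimization finds local optima; restarts and neighbor
  warm-starts mitigate but do not guarantee global optimality.
* Deconvolution degrades jointly with low proportion variability and high
  noise (v = 100 with sd 0.2 is effectively unidentifiable); the CVE
  surface flags this as a flat, high error but cannot repair it.
* No missing-value handling: rows with missing or out-of-range entries
  are rejected on input, not imputed.
* Probe annotation, genomic mapping, and gene-set enrichment of
  component-specific CpGs are out of scope; the specific-CpG tables are
  intended to feed external annotation tools.
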