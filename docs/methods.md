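# Methods

## Model, statistic, decision rule

A model is a polynomial steady-state system `f(a, x) = 0` (parameters
`a ∈ R^k`, states `x ∈ R^n`) with polynomial outputs `z = g(x) ∈ R^m`,
`m ≤ n`. An observation is `y = z + ε` with independent Gaussian errors
`εᵢ ~ N(0, σᵢ²)`, the variances known (instrument calibration). Writing
`V_M` for the model variety `{f = 0, z − g(x) = 0}` in `(a, x, z)` space
and `V_D` for the affine data variety fixing observed outputs to `y`, the
fit statistic is the minimum weighted squared distance

    d² = min_{(a,x,z) ∈ V_M} Σ_{i observed} (zᵢ − yᵢ)² / σᵢ².

Minimizing this subject to the variety constraints is exactly maximizing
the Gaussian log-likelihood, so the argmin `(â, x̂, ẑ)` is the
maximum-likelihood estimate of parameters, hidden states and de-noised
outputs. Under the null hypothesis the distribution of d² is dominated
by `χ²_m` with `m` = number of observed outputs (not m minus free
parameters: the test is a conservative dominance bound, not an asymptotic
likelihood-ratio test), so the decision rule is `d² ≤ χ²_{m,α}` ⇒
compatible. Validation applies this rule; selection ranks surviving
models by (optionally AIC-penalized, `d² + 2·#free parameters`) d²;
estimation skips the α decision and returns every global argmin.

**Reporting units.** When all observed variances share a common value σ²
the report shows the plain squared distance and the rescaled threshold
`p_α = σ²·χ²_{m,α}` (the form worked examples print); with heterogeneous
variances it shows the weighted statistic and the raw quantile. The
decision is identical either way, and both numbers are carried in the
`FitReport` (`d2`, `d2_weighted`).

## Finding all critical points

Local optimizers can stall in local minima, so the package computes
*every* critical point of the distance. The first-order conditions are
assembled as a Fritz John system: the constraints
`F = {f(a, x), z − g(x)}` (r + m polynomials), the gradient equations
`λ₀ ∇obj + Σⱼ λⱼ ∇Fⱼ = 0` over all free coordinates, and one random
complex affine chart `Σ cⱼ λⱼ = 1` normalizing the projective multiplier
vector. Using a chart rather than pinning `λ₀ = 1` retains degenerate
extrema with `λ₀ = 0`; those points are excluded from ED-degree counts
(which concern critical points of a *generic* external point) but are
tracked and reported. Because λ is projective, the objective may be
rescaled freely inside the system; the implementation normalizes the
largest weight to 1, which keeps coefficients well conditioned when
error variances are small (σ² = 10⁻⁴ gives raw weights of 10⁴, enough to
break double-precision tracking without this normalization). Unobserved
outputs get weight zero and keep their constrained z variable, so
partial observation shares one code path with full observation.

The square augmented system is solved by polynomial homotopy
continuation:

- **Start system.** Total-degree: `x_i^{d_i} − 1 = 0` with its `∏ d_i`
  roots of unity, deformed along `H(x, t) = (1−t)·γ·S(x) + t·T(x)`.
  The random unit complex γ (drawn from the seed) keeps paths off the
  discriminant with probability one.
- **Tracking.** Adaptive step in t with a 4th-order explicit (RK4)
  predictor on the Davidenko equation and a Newton corrector (tolerance
  1e−10, ≤ 3 iterations). Steps halve on corrector failure and double
  after 5 consecutive successes, clamped to [1e−12, 0.1]; a path is
  abandoned after 10 consecutive halvings (near-misses close to t = 1
  are rescued by the endpoint polish below) and declared divergent when
  a coordinate exceeds 1e8 (affine tracking with a cutoff, not
  projective tracking — adequate at these problem sizes and simpler).
- **Endpoints.** Converged paths get a final Newton polish at t = 1
  (residual contract |T| < 1e−8); endpoints with a numerically
  rank-deficient Jacobian are flagged singular. Endpoints are
  deduplicated by greedy clustering at relative tolerance 1e−6 in the
  max norm; cluster sizes serve as multiplicity estimates. Singularity
  here is diagnostic, not certified — the decision algorithms need
  counts and minima, not certified multiplicities, which is why
  tracking stays in double precision throughout with no multiprecision
  endgame.
- **Path accounting.** converged (with multiplicity) + diverged +
  failed = number of start paths, asserted in tests over random
  systems.
- **Real filter.** A critical point is real when the imaginary parts of
  its `(a, x, z)` block are below 1e−6·(1+|Re|). The multiplier block is
  excluded from this test: the complex chart makes λ non-real even at
  real critical points.
- **Parameter homotopy.** The critical system depends on the data `y`
  only through the gradient equations, linearly. Solving once at a
  generic *complex* data point and tracking the finite nonsingular
  solutions along a straight segment in data space solves every further
  data point at the cost of ED-degree-many paths (used by the repeated
  recovery experiments; consistency with fresh solves is asserted to
  1e−6 over 50 random targets).

All paths of a solve advance in lockstep: predictor/corrector linear
algebra is batched across paths (one NumPy/LAPACK call per step over all
active paths, sparse matrix–matrix products for the polynomial
Jacobians), with per-path adaptive steps. This is what makes a
pure-Python tracker practical at a few thousand paths.

## Intersections and dimension

Before minimizing, validation checks whether the varieties intersect, in
the `(a_free, x)` chart (`{f = 0, g_obs(x) − y_obs = 0}`):

- square system → solve; real solutions ⇒ compatible with d² = 0;
- overdetermined → replace by #vars random complex combinations
  (solutions of the original survive; extras are residual-filtered);
- underdetermined → dimension by random-slice probing: the dimension is
  the largest d for which d generic affine hyperplanes leave a finite
  nonempty solution set (slices use real coefficients from the seeded
  generator, generic enough with probability one).

A positive-dimensional intersection yields the decision **possibly**:
deciding whether such a component contains a real point is a hard
semialgebraic problem, and this package deliberately returns the guarded
answer rather than certifying (a documented heuristic; the
zero-dimensional case is decided exactly). The same guarded answer is
produced when the critical set itself is degenerate (clustered /
rank-deficient endpoints).

Non-negativity constraints (concentrations, rates) are honored by
filtering real critical points to the closed orthant in `(a, x)` and
additionally solving boundary subsystems with up to B = 2 free variables
pinned to zero — a tractable surrogate for fully constrained Fritz John
systems; B is a parameter (`boundary_cap`) and the cap is the documented
limitation.

## Reaction-network frontend

`parse_network` reads one reaction per line (`A + 2 B -> C, k1`;
`A <-> B, kf, kr` expands to a pair). Steady-state polynomials follow
mass action exactly: `f_s = Σ_r (prod_{r,s} − react_{r,s})·k_r·Π_u
x_u^{react_{r,u}}`. Conservation laws are an integer basis of the left
null space of the stoichiometric matrix (fraction-free scaling, with a
greedy basis change preferring nonnegative, moiety-style coefficients);
`network_to_model` keeps a full-rank subset of the steady-state rows and
appends one conservation relation `Σ c_s x_s − T_j` per dependency, so
the Fritz John construction sees constraints of full rank. Totals `T_j`
are bound as knowns when measured and left as free parameters otherwise.

## Synthetic data and fixtures

Steady states are produced by stiff integration (BDF) of the mass-action
ODEs followed by a terminal Newton polish on the full-rank steady-state
system, so `|f| < 1e−8` is guaranteed or an error is raised.
Observations add i.i.d. Gaussian noise with recorded variances; rate
constants and initial conditions, where not pinned by a fixture, are
drawn i.i.d. lognormal(0, 1), the standard heavy-tailed choice for
positive kinetic constants.

Bundled fixtures and the conditions the experiments run at:

- **Ellipsoid scenarios** (`builtin_examples`): unit sphere, outputs
  (x, y), σ² = 0.1, α = 0.1; four observation cases with expected
  decisions compatible / possibly / incompatible / compatible.
- **Two-species conversion** `A ⇌ B` (k1 = 1, k2 = 2, total T = 3,
  σ = 0.1): the model variety is a single point in output space, making
  the weighted d² exactly χ²₂-distributed under the null — the type-I
  calibration fixture (500 replicates; rejection rate must stay within
  α + 3·SE).
- **Interaction trio**: three 2-species circuits sharing basal
  synthesis/degradation (k1 = 2, d1 = 1, k2 = 3, d2 = 1, measured) and
  differing only in the coupling reaction — mutual annihilation,
  P2-catalysed removal of P1, P1-catalysed removal of P2 — with the
  coupling rate γ unknown (true value 1). Data simulated from the
  second at σ = 0.05; selection must recover it. These are synthetic
  study systems built for this package: they reproduce the *shape* of
  published bistable-circuit discrimination experiments at sizes where
  a dense total-degree solve is exact and fast (the published 7–8
  species circuits have critical-system Bézout counts ≥ 10⁵, beyond a
  dense total-degree strategy; solving them needs start-system
  engineering such as regeneration, out of scope here).
- **Viral dynamics** (T, I, V with infection k·T·V, production p·I,
  clearance dV·V; s = 10, d1 = 0.1, k = 0.1, d2 = 0.5, p = 5, dV = 3):
  the clearance rate dV is the single unknown recovered from
  steady-state data with σ = 0.1 absolute noise; over 20 seeds the
  median recovery error is ~0.2%, well within the 10% requirement.

What these fixtures do not emulate: correlated or non-Gaussian
measurement error, model misspecification beyond the candidate set,
multistationarity (each fixture has a unique positive steady state in
its compatibility class), and the scale of published signalling models.
Passing tests therefore demonstrate correctness of the machinery at
small-to-moderate algebraic complexity, not performance at Bézout counts
beyond ~10⁴.

## Numerical choices, at a glance

| quantity | default | note |
| --- | --- | --- |
| corrector tolerance | 1e−10 | per Newton step, relative |
| endpoint residual | 1e−8 | converged-solution contract |
| dedup / real tolerance | 1e−6 | relative, max norm |
| initial / max / min step | 0.05 / 0.1 / 1e−12 | on t ∈ [0, 1] |
| divergence cutoff | 1e8 | max coordinate magnitude |
| consecutive failure cap | 10 | then endpoint-polish rescue |
| boundary cap B | 2 | orthant boundary subsystems |
| ED-degree λ₀ cutoff | 1e−6·max|λ| | excludes degenerate stratum |

All randomness (gamma, multiplier chart, generic data points, slices,
square-up combinations, noise) flows from integer seeds; two solves with
different seeds must agree on the deduplicated solution set (asserted),
and a solve whose paths all fail is retried once with a fresh gamma
before raising.

Tie-breaking in selection is deterministic: smaller penalized d², then
fewer free parameters, then declared order. Ranking across models
compares the weighted statistic, which is the comparable quantity when
models share the data.

## Known limitations

- Total-degree start systems track `∏ dᵢ` paths; multihomogeneous or
  regeneration start systems are not implemented, which bounds the
  practical model size (joint fits over many data points grow fastest).
- Real points on positive-dimensional intersections are not certified;
  the pipeline reports "possibly" instead.
- Singular endpoints are clustered and flagged, not certified
  (no multiprecision endgame, no alpha-theory certification).
- The orthant-constrained minimum sweeps boundary strata only up to
  codimension B.
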