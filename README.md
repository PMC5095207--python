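# varfit

Global model validation, selection and maximum-likelihood estimation for
polynomial steady-state models, via numerical algebraic geometry.

## The problem

Many deterministic models in systems biology — mass-action chemical
reaction networks above all — are polynomial at steady state: the dynamics
`dx/dt = f(a, x)` with rate parameters `a = (a₁, …, a_k)` and species
concentrations `x = (x₁, …, x_n)` are studied on `f(a, x) = 0`, and
experiments measure polynomial outputs `z = g(x)` (usually a subset of the
concentrations). Given a noisy observation `y` of those outputs with known
error variances `σᵢ²`, three questions arise:

1. **Validation** — is the model compatible with the data?
2. **Selection** — which of several candidate models fits best?
3. **Estimation** — what are the maximum-likelihood parameter and
   hidden-variable values?

All three reduce to the same geometric computation. The *model variety*
is the solution set of `{f(a, x) = 0, z − g(x) = 0}` in the joint
`(a, x, z)` space; the *data variety* is the affine subspace fixing the
observed outputs to `y`. The goodness-of-fit statistic is

    d² = min Σᵢ (zᵢ − yᵢ)² / σᵢ²   subject to  f(a, x) = 0, z = g(x),

the minimum weighted squared distance between the two varieties. Under
the null hypothesis (data generated by the model with Gaussian errors)
the distribution of d² is dominated by χ² with m degrees of freedom,
m = number of observed outputs, so `d² > χ²_{m,α}` rejects the model at
level α. The minimizing point `(â, x̂, ẑ)` is the maximum-likelihood
estimate.

The objective is non-convex with many local minima. Instead of local
descent, varfit assembles the Fritz John first-order optimality system —
the constraints together with

    λ₀ ∇obj(a, x, z) + Σⱼ λⱼ ∇Fⱼ(a, x, z) = 0,

with the multiplier vector λ treated projectively via a random affine
chart — and finds **all** of its isolated complex solutions by polynomial
homotopy continuation (total-degree start system, gamma trick, adaptive
RK4 predictor / Newton corrector). Filtering to real points and taking
the smallest objective value yields the global minimum with probability
one over the random choices. The number of critical points for generic
data — the Euclidean distance degree (ED degree) of the variety — bounds
the number of paths a parameter homotopy must track when the same model
is fitted to many data points.

## Worked example

The unit sphere `x² + y² + z² = 1` with outputs `(x, y)` observed, common
error variance σ² = 0.1, and the observation `y = (1.7, 0)`:

```python
from varfit import DataPoint, validate
from varfit.synthdata import ellipsoid_model

model = ellipsoid_model()          # unit sphere, outputs (x, y)
data = DataPoint([1.7, 0.0], [0.1, 0.1])
report = validate(model, data, alpha=0.1)
print(f"decision : {report.decision}")
print(f"d2       : {report.d2:.4f}")
print(f"p_alpha  : {report.p_alpha:.4f}")
est = report.estimates[0]
print(f"nearest model point : ({est['states']['x']:.3f}, "
      f"{est['states']['y']:.3f}, {est['states']['z']:.3f})")
```

prints

```
decision : incompatible
d2       : 0.4900
p_alpha  : 0.4605
nearest model point : (1.000, -0.000, -0.000)
```

The nearest point on the sphere to the data point (1.7, 0, free) is
(1, 0, 0), so the squared distance is 0.49; with σ² common to all
outputs, d² is reported in plain squared-distance units and the threshold
is p_α = σ²·χ²₍₂,₀.₁₎ = 0.1 × 4.6052 = 0.4605. Since 0.49 > 0.4605 the
model is rejected at the 10% level. Moving the observation to (1.01, 0)
gives d² = 10⁻⁴ and a compatible verdict; observing (0, 0) puts the data
variety through the sphere (two real intersection points (0, 0, ±1),
d² = 0); observing only x′ = 0 leaves a positive-dimensional
intersection, where the honest answer is "possibly compatible".

Reaction networks come in through a plain-text format:

```python
from varfit import parse_network, network_to_model, estimate

net = parse_network("A <-> B, k1, k2")
model = network_to_model(net, measured=("A", "B"),
                         known={"k1": 1.0, "T1": 3.0})  # k2 unknown
```

`network_to_model` derives the mass-action steady-state polynomials,
replaces rank-deficient rows by conservation laws (`A + B = T1` here),
and exposes unknown rates and totals as free parameters for `estimate`.

A `varfit` command-line tool wraps the same operations
(`varfit validate MODEL.json DATA.csv --alpha 0.1`, `varfit ed-degree`,
`varfit select`, `varfit estimate`, `varfit crn2model`,
`varfit make-fixtures`); `validate` exits 0/1/2 for
compatible/incompatible/possibly.

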