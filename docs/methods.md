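# Methods

## Model

The package studies a planar dynamical system on the unit square
`(x, r) ∈ [0,1]²` coupling the replicator dynamics of a threshold
public-goods game to a dynamic risk of collective failure:

```
ε ẋ = x(1−x) [ Γ(x) r b − c ]
  ṙ = r(1−r) K(x)
```

* `x` — frequency of cooperators in an infinite well-mixed population.
* `r` — probability that the group loses its remaining endowments when
  fewer than `M` of the `N` group members cooperate.
* `Γ(x) = C(N−1,M−1) x^(M−1) (1−x)^(N−M)` — the pivotality kernel: the
  probability that a focal player has exactly `M−1` cooperating
  co-players, which is the only composition at which its own contribution
  changes the group outcome. The closed-form payoff advantage of
  cooperation, `f_C − f_D = Γ(x) r b − c`, follows because cooperating
  pays `rb − c` at the pivotal composition and `−c` at every other; the
  exact binomial expectation (`average_payoffs`) is kept as an independent
  oracle and the identity is asserted to 1e−12 in the tests.
* `K(x)` — the strategy-to-risk feedback kernel: `u(1−x) − x` (linear;
  defection raises risk at rate `u`, cooperation lowers it at unit rate)
  or `B(x−T) = −tanh(β(x−T)/2)` (sigmoid; risk falls once cooperation
  exceeds the threshold `T`, with steepness `β`). The logistic factor
  `r(1−r)` pins `r` inside `[0,1]`, and `x(1−x)` does the same for `x`,
  so the unit square is forward invariant.
* `ε > 0` — relative speed of strategy updating; `ε ≪ 1` means strategies
  move much faster than the risk. It rescales `ẋ` only, so equilibria,
  stability signs and Hopf thresholds are independent of it; this
  invariance is covered by dedicated tests at `ε ∈ {0.01, 0.1, 1}`.

Model assumptions worth keeping in mind: infinite population (no
demographic noise), groups resampled every instant (no repeated
interaction), a single risk variable shared by the whole population, and
feedback acting through the current cooperator frequency only (no memory
or delay).

## Equilibrium structure and stability

Both feedback laws share the same skeleton: four corner equilibria, up to
two boundary equilibria `(x₁*,1), (x₂*,1)` where `Γ(x)b = c` (found by
bisection on the two flanks of the unimodal `Γ`, to ~1e−14), and at most
one interior equilibrium at the zero of `K` — `x = u/(1+u)` or `x = T` —
with equilibrium risk `c/(Γ(x)b)`, which exists only while that risk is
strictly below 1. At equality the interior point collapses onto the
boundary root and is reported once, as a boundary point.

Stability comes from the analytic Jacobian (entries listed in
`riskcoev.dynamics.jacobian`; verified against central finite differences
in the tests). Eigenvalue real parts within 1e−9 of zero are treated as
zero: a purely imaginary pair is labelled `center_hopf`, a single zero
eigenvalue `marginal_degenerate`. The degenerate coincidence
`x₂* = u/(1+u)` is *flagged*, not resolved — a center-manifold argument
would be needed and simulation is the supported way to probe it.

At the interior point the Jacobian has zero lower-right entry and
off-diagonal entries of opposite sign, so its trace equals
`x(1−x) Γ'(x) r b / ε` and its determinant is positive: stability is
decided by the sign of `Γ'` at the interior `x`. The trace vanishes
exactly when the interior `x` sits at the mode `(M−1)/(N−1)` of `Γ`,
giving closed-form Hopf thresholds `u = (M−1)/(N−M)` (linear) and
`T = (M−1)/(N−1)` (sigmoid). `hopf_threshold_numeric` re-derives these by
Brent root-finding on the trace, and tests require agreement to 1e−10
over a grid of `(N, M)`.

The `(u, c/b)` and `(T, c/b)` parameter planes are classified into four
outcome regions (`classify_region`): `bistable_interior` (stable interior
point coexisting with the all-defect corner `(0,1)`), `hopf_line` (the
measure-zero threshold, carrying the stable limit cycle),
`defection_only`, and `bistable_boundary` (stable `(x₂*,1)` when
`x₂*` lies below the risk balance point). `(0,1)` is stable in every
region — the tragedy of the commons is never escapable globally, only
avoidable from favourable initial conditions.

## First Lyapunov coefficient

`first_lyapunov_coefficient` decides the criticality of the Hopf
bifurcation. The field is translated to the interior fixed point and
linearly rescaled (the `r` deviation divided by `J₂₁/ω`, `ω = √det J`) so
the linear part becomes the standard rotation; the planar normal-form
combination of second- and third-order partial derivatives of the
transformed field then yields ℓ₁. Partials are computed with
fourth-order-accurate central difference stencils (step 1e−2; truncation
~h⁴ and round-off ~eps/h³ both far below the measured magnitude).
Only the *sign* of ℓ₁ is contractual: both reference systems give
ℓ₁ ≈ −5e−6 < 0, i.e. supercritical bifurcations with stable cycles. The
function refuses to run when |trace| > 1e−8 at the interior point, since
the normal-form reduction is meaningless off the threshold.

## Trajectories and attractor detection

Integration uses LSODA (adaptive, stiffness-switching — small `ε` makes
the replicator layer fast relative to the risk layer) with
`rtol = atol = 1e−10`, sampled at 10 points per time unit, default
horizon 2000 time units and 5000 near the Hopf threshold where
transients decay slowly. States are clipped to the unit square after
integration and the cumulative clip magnitude is recorded on the
trajectory (observed ≲1e−9, consistent with the forward-invariance
analysis).

Attractor detection examines the last quarter of the run: a terminal
state with residual field norm below 1e−8 matching a catalogued
equilibrium to 1e−4 is a fixed point; an `x` oscillation holding an
amplitude above 1e−3 with at least five peaks (refractory window 1% of
the analysis span) whose heights vary by under 5% is a limit cycle, with
the period estimated as the mean inter-peak interval; anything else is
reported as undetermined with a diagnostic. Basin maps integrate a
uniform grid strictly inside the square (offsets `k/(R+1)`; the
boundaries are invariant) in chunks with early stopping once a state
parks on an equilibrium, at relaxed tolerance 1e−8 since only the
attractor identity matters.

## The near-degenerate Hopf and the amplitude ladder

ℓ₁ is four orders of magnitude smaller than the other coefficients of the
normal form, so the system is *nearly conservative* at the threshold.
Two practical consequences shape the numerical protocol:

* Exactly at the threshold, orbits decay toward the interior focus only
  algebraically and imperceptibly over thousands of time units; a
  trajectory started at the reference initial condition (0.4, 0.3) is
  observed — and reported — as a stable small-amplitude oscillation.
* The window below the threshold in which the Hopf-born cycle still fits
  inside the unit square is narrow (about 1e−3 in the bifurcation
  parameter); further out, the slowly growing spiral escapes the interior
  and is captured by the all-defect corner. The supercritical signature
  is therefore measured with a five-point parameter ladder spanning the
  last 1e−3 below the threshold (`cycle_amplitude_ladder`, default
  horizon 2000 time units from (0.4, 0.3)): the measured `x` amplitude
  over the final quarter of each run shrinks monotonically to zero as the
  threshold is approached, as required for a supercritical bifurcation.
  These are finite-time amplitudes from a fixed initial condition and
  horizon — near so degenerate a Hopf point, fully converged asymptotic
  amplitudes are unreachable at any realistic integration length, and the
  monotone trend is the meaningful observable.

## Problem sizes and defaults

The study conditions are the reference game `N=6, M=3, b=1, c=0.1` with
`ε=0.1`, the linear rates `u ∈ {0.5, 2/3, 2, 4}` and sigmoid thresholds
`T ∈ {0.2, 0.4, 0.5, 0.8}` shipped as presets. The sigmoid steepness for
the presets is `β = 10` — large enough for a clearly switch-like response
while far from the step limit; the Hopf threshold in `T` is independent
of `β` for any `β > 0`, so this choice affects transients and cycle
shape, not the catalogue of outcomes. Property tests sample group sizes
up to `N = 20` (payoff identity) and `N ≤ 12` threshold grids (Hopf
agreement); binomial coefficients are computed in exact integer
arithmetic, with a log-space evaluation of `Γ` above `N = 50` to avoid
overflow. Basin maps in the tests use small grids (5×5) with a
1000-time-unit horizon; the CLI defaults to 11×11 and 2000 units.

## Known limitations

* The generic cases are classified analytically; the non-generic
  coincidences (parameter exactly on the Hopf line, `x₂* = u/(1+u)`,
  equilibrium risk exactly 1) are flagged (`center_hopf`,
  `marginal_degenerate`, collapse onto the boundary) rather than resolved
  by higher-order analysis.
* Custom feedback kernels are integrated and differentiated numerically
  but excluded from analytic equilibrium enumeration and region
  classification.
* No continuation of the limit-cycle branch away from the threshold, and
  no detection of global (homoclinic/heteroclinic) bifurcations; the
  trajectory engine is the probe for those regimes.
* The model itself is deterministic and unstructured: no finite-population
  noise, network structure, time delays, or multiple interacting feedback
  loops.
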