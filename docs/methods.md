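# Methods

## Model representation

A `NetworkModel` is a semi-explicit index-1 differential-algebraic system
over a fixed ordered set of named states.  Each state is exactly one of:
`ode` (d[x]/dt = f), `implicit_algebraic` (0 = g), `explicit_algebraic`
(x = h, evaluated in dependency order), or `parameterized` (held at a
parameter value).  Concentrations are µM, time is seconds; first-order
rates are s⁻¹ and zeroth-order fluxes µM s⁻¹.  Models are preferably built
from sympy expression strings (programmatically or from the declarative
text format in `phasereduce.modelfile`), because the expressions' free
symbols give exact state-dependency sets; these drive both the topological
ordering of explicit states and the enumeration of *direct* species pairs
used for reduction decisions.  Raw-callable models are supported but must
supply dependencies explicitly to use the direct-pair machinery.

The bundled toy pathway is the linear irreversible chain
source → A → B → C → sink, first-order mass action with k2 = 1 s⁻¹,
k3 = 10 s⁻¹, k4 = 1 s⁻¹ and a switchable zeroth-order source of
100 µM s⁻¹.  The source is zeroth-order by dimensional necessity — a
first-order source would require a substrate species the topology does not
contain — and gives the finite stimulated steady state (A, B, C) =
(100, 10, 100) µM with B = (k2/k3)·A.

## Transient protocol and integration

All timescale analysis uses a single on/off input switch.  Integration is
piecewise over the on and off segments with the switched parameter updated
between them, so the stiff solver never sees a discontinuous right-hand
side.  The integrator is BDF with rtol 1e-8 and atol 1e-10 µM.  Implicit
algebraic states are re-solved at every right-hand-side evaluation with a
warm-started Powell hybrid root solve; convergence is judged by the
residual itself, not only the solver's status flag, because MINPACK's
relatively scaled finite-difference steps stall on denormally small warm
starts (the solve is retried from zero and from a unit guess before
failing).  Trajectories are checked for positivity (tolerance −1e-7 µM)
and declared conservation totals (relative tolerance 1e-6) at every output
sample.

The default output grid is 2,000 uniform samples over the combined on+off
window.  The loop-area integral needs no uniform spacing; the density is
chosen so that doubling it changes any toy-pair area by < 1e-3 (asserted
in the test suite as grid convergence).

Steady states are found by integrating over geometrically growing horizons
until the scale-free criterion max |dx/dt| / max(|x|, 1 µM) < 1e-8 s⁻¹,
then polishing with a root solve on the stacked derivative+residual
system; divergence (any state beyond 1e9 µM) and non-convergence are
distinct, explicit errors.

## Normalization and loop areas

Each trace is affinely rescaled by its own sample min/max onto [0, 1];
the (x_min, x_max) pair is retained for exact de-normalization.  A trace
with numerically zero dynamic range cannot be rescaled and is flagged
static and excluded from phase analysis rather than divided by zero.

The hysteresis area of the closed polygonal loop through the normalized
points is |Σ_i ½(Y_{i+1}+Y_i)(X_{i+1}−X_i)| with the last segment wrapping
to the first point — the trapezoid/shoelace rule, exact for polygons,
invariant under cyclic rotation and axis swap, and correct across
concavity changes.  Self-intersecting loops (which arise for adaptive
responses) cancel in the signed sum; `split_loop_area` optionally detects
proper segment crossings, splits the polygon, and sums absolute sub-areas.
The signed-magnitude form is the default because it is the direct reading
of the line-integral definition; the split variant is quadratic in the
point count and intended for per-pair diagnostics.

Classification bins are fast [0, 0.05], medium (0.05, 0.5], slow (0.5, 1]:
closed upper boundaries, so an area of exactly 0.05 is fast.  The
histogram bin width defaults to 0.05.  The thresholds are the empirical
trimodal cut points of the reference signaling network; they are
parameters (`SpeedThresholds`), not constants — the toy pathway's A–B pair
(area 0.091) illustrates why, sitting just above the default fast cut even
though it is the chain's unambiguous quasi-steady pair.  Toy demonstrations
therefore use a 0.1 threshold.

## Concentration clamps and relation fitting

Clamping literally freezes a state: its kind becomes `parameterized`, its
equation is dropped, and the remaining system is relaxed to steady state
under the fixed stimulus context.  The sweep default is 25 linear points
from 0 to 1.5× the state's maximum over the reference transient (slightly
beyond the observed range, to limit extrapolation of the fitted law);
logarithmic spacing is available.  Sweep points whose steady-state search
fails or violates conservation are flagged and kept as NaN, never silently
dropped.

Candidate forms are Hill `y_max·x^h/(K^h+x^h)` (baseline fixed at 0),
linear, saturating exponential `a·(1−e^(−r·x))+c`, and power `c·x^e`.
Fitting is Levenberg–Marquardt (lmfit); Hill starts at y_max = max
response, K = abscissa at half-max, h = 1, with a multi-start over
h ∈ {0.5, 1, 2, 4}.  Selection is by least rmse, with numerical ties
(within a 1e-6 relative + tiny absolute band) broken toward the most
parsimonious form (linear ≺ power ≺ exponential ≺ Hill), so exactly linear
data yields the linear law rather than a degenerate power fit.  Selection
can be constrained per pair by passing a single candidate.  Fits carry
their sweep domain; evaluation outside it is flagged (or refused on
request).

## Reduction plans and scoring

`propose_plan` reduces the downstream state of every direct pair with area
at or below the threshold (the state whose equation references the other;
at most one reduction per state, keyed to its smallest-area pair).
Mutually dependent (reversible) pairs are *not* auto-reduced — the
direction of replacement is a modeling judgment — and are recorded in the
plan notes for user intervention.  Model-specific simplifications
(conservation-of-mass elimination, free≈total, negligible or equal
species) are user-declared `ReductionAction`s, since the area matrix alone
cannot justify them.  Plans reject cyclic reduction dependencies with the
cycle reported.

`apply_plan` keeps every state in the model: reduced states become
explicit, evaluated in dependency order so chained reductions compose, and
fitted relations also serialize to closed-form expressions so reduced
models round-trip through the declarative text format.

Accuracy is mean over output times of |x_red − x_orig| divided by the
original state's dynamic range over the protocol, ×100 — the same
range-normalization convention as the loop analysis.  A pointwise-relative
variant (floor 1e-3 µM) is available behind `metric="relative"`.  States
fixed under the protocol or removed by the plan are excluded by the
caller; a state silently missing from either model's output is an error.
The perturbation suite re-scores under new scenarios and reports scenario
parameters that are structurally absent from the reduced model as
`insensitive_params` (the reduced model cannot respond to them — itself a
diagnostic finding), injecting the parameter inertly so both models still
simulate on the same grid.

## Jacobian modal analysis

The Jacobian is the central finite-difference linearization of the stacked
ODE-derivative + algebraic-residual system over the dynamic states, with
step cbrt(eps)·max(|y|, 1) per column and explicit/parameterized states
re-evaluated at every perturbation.  It refuses states that are not at
steady state (normalized rate > 1e-6 s⁻¹).

Modes are rows of M⁻¹ from J = MΛM⁻¹, unit-normalized, reported slowest
first with τ = −1/Re(λ); entries above the 0.09 magnitude threshold are
the mode's dominant species.  State variables are not rescaled before
thresholding (the threshold's meaning depends on this choice; unscaled is
the documented default).  Complex-conjugate pairs are merged into one mode
with the shared τ and the union of dominant species.  Modes with
τ ≤ 1 ms are labeled algebraic-relationship modes.  A near-defective
eigenvector matrix (condition > 1e12) flags the report `unreliable` and
falls back to a pseudoinverse for the modal rows: eigenvalues and
timescales remain exact, dominant-species lists do not.  The toy pathway
is itself such a case — its eigenvalue −1 s⁻¹ has algebraic multiplicity 2
but a one-dimensional eigenspace — so the reconstruction identity
‖MΛM⁻¹ − J‖/‖J‖ < 1e-8 is verified on distinct-rate chains, where M is
well-conditioned.

## Synthetic cascade generator

`generate_cascade` materializes a linear mass-action chain X1 → … → Xn →
sink with a switchable zeroth-order source (default 100 µM s⁻¹, matching
the toy's stimulus magnitude).  Its Jacobian is lower-bidiagonal with
eigenvalues equal to minus the rate ladder, so every timescale is known
analytically.  `random_cascade_spec` draws rates log-uniformly over
10^[−0.5, 2] s⁻¹ (≈0.3–100 s⁻¹, allowing up to ~300-fold separation
between adjacent steps — wide enough that fast, medium and slow pairs all
occur), deterministically per seed.  Benchmark protocols scale the
stimulus window to 5 relaxation times of the slowest step.

What the generator emulates: stiff first-order cascades with controllable
rate separation, the regime in which quasi-steady-state reduction is
provably well-behaved.  What it does not emulate: saturating (Michaelian
or Hill-type) kinetics, feedback loops, conservation-coupled cycles, or
measurement noise.  Passing the cascade benchmarks therefore demonstrates
correctness of the pipeline's mechanics and the monotone accuracy/
aggressiveness trade-off; it does not by itself certify accuracy on
strongly nonlinear networks, where the clamp curves are nonlinear and the
fitted-form choice matters.

## The β-adrenergic fixture

The reference 25-variable signaling model (12 ODE + 13 implicit states)
and its 6- and 4-variable reductions are published only in supplementary
material that cannot be bundled; `phasereduce.betaadrenergic` ships the
loading contract instead.  Transcriptions are declarative model files —
data, reviewable line-by-line against their source, not hand-written code
— validated on load against the published structure (state counts; the
six retained ODE species of the mid-size reduction).  A missing
transcription raises `FixtureUnavailableError` with guidance; nothing
falls back silently.  The five published stimulus scenarios (1 µM and
0.05 µM isoproterenol, 10 µM forskolin, 100 µM IBMX, transient
phosphatase-1 knockout; 400 s on + 400 s off) are defined in code because
their magnitudes are fully published.

## Numerical choices and degenerate inputs, collected

- Integration: BDF, rtol 1e-8, atol 1e-10 µM; piecewise over the switch.
- Steady state: normalized-rate < 1e-8 s⁻¹ + root polish; divergence cap
  1e9 µM; round-off negatives above −1e-9 clipped to 0.
- Areas: grid-converged at 2,000 samples (< 1e-3 drift on doubling);
  loops need ≥ 3 finite points.
- Static traces (range ≤ 1e-9 relative): flagged, excluded, never divided.
- Classification boundaries closed above; exactly 0.05 is fast.
- Fit ties broken toward parsimony; Hill constrained to K > 0, h > 0.
- Plan cycles and duplicate per-state actions rejected at construction.
- Defective Jacobians flagged, pseudoinverse modal rows, exact timescales.

## Known limitations

- The clamp procedure assumes a unique stable steady state of the clamped
  subsystem at each sweep value; multistable systems (non-closed phase
  loops) are outside the method's assumptions, and non-convergent sweep
  points are surfaced rather than resolved.
- Oscillatory systems would close phase loops without an external switch;
  the protocol machinery does not yet exploit this.
- `split_loop_area` is O(n²) in loop points; use it per pair, not on the
  full matrix.
- CellML import only enumerates variables to aid manual transcription;
  MathML translation is not attempted.
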