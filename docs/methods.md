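# Methods

## Model family

The core is the two-population power-law model of a bone remodeling unit:
osteoclasts `x1` and osteoblasts `x2` with production terms
`α_i·x1^{g1i}·x2^{g2i}` and linear removal `β_i·x_i`.  The exponents
`g_ij` encode net autocrine (`g11`, `g22`) and paracrine (`g12`, `g21`)
signalling; with the canonical physiological constants (α1=3, α2=4,
β1=0.2, β2=0.02, g11=1.1, g21=−0.5, g12=1, g22=0, all rates per day) the
system orbits a nontrivial fixed point in a sustained oscillation.  Bone
mass `z` (percent of initial) integrates `−k1·y1 + k2·y2` where
`y_i = max(x_i − x̄_i, 0)` is the half-rectified excess over the
reference fixed point and `k1 = 0.093`, `k2 = 0.0008` %/cell/day.

Tumor burden is a normalized Gompertz variable,
`dD/dt = μ·D·log10(σ/D)`, with proliferation rate `μ` (default
0.005/day) and asymptote `σ ∈ (0,1)`.  The base-10 logarithm is a
deliberate modeling convention: it makes the tumor eigenvalue of every
Jacobian exactly `−μ/ln 10`, which the stability module asserts to
machine precision.  `D = 0` is a removable singularity (rate 0), so
extinction is an unstable fixed point; runs start from a strictly
positive `D0`, default `0.005·σ` (the initial burden is a run-level
knob; the long-run behavior is insensitive to it because `ln(D/σ)`
decays at the fixed rate `μ/ln 10`).

Three couplings are implemented behind one canonical coefficient form
`A_i(D)·x1^{G1i(D)}·x2^{G2i(D)} − B_i(D)·x_i`:

* **Model 1** multiplies or divides each of `α1, α2, β1, β2` by `(1−D)`
  according to a nine-row scenario table (encoded as data, one row per
  scenario, so there is a single source of truth rather than nine
  hand-written right-hand sides).
* **Model 2** multiplies the production terms by `D^{g31}` and
  `D^{g32}`.
* **Model 3** deforms the exponents:
  `g̃11 = g11(1+r11·D/σ)`, `g̃21 = g21(1+r21·D/σ)`,
  `g̃12 = g12/(1+r12·D/σ)`, `g̃22 = g22 − r22·D/σ` (requires
  `r12 > −1` so the denominator cannot vanish for `D ≤ σ`).

## Steady states

All closed forms are powers of the ratios `β1/α1` and `β2/α2`, with
`γ = g12·g21 − (1−g11)(1−g22)` (or its model-3 analogue Λ with the
deformed exponents at `D = σ`) in the denominators of the exponents;
`γ = 0` raises an explicit undefined-steady-state error.  Powers are
evaluated as `exp(e·log(ratio))` on strictly positive ratios — negative
bases are a validation error, never silently complex.  Model-1 scenario
factors are encoded as per-scenario exponent pairs of `(1−σ)`;
scenarios 0–2 cancel exactly (the same `(1−D)` factor enters `α` and
`β`).  Values printed by reporting surfaces are rounded to 4 decimals;
internal computation is full double precision.

**Model-2 conventions.**  Two forms of the model-2 `x̄1` are provided.
The default ("as-printed") carries the tumor factor
`σ^{(g31−g31·g22−g21·g32)/γ}` and is the reference form used by the
worked examples and by the stability-region classifications; the
`self_consistent=True` form carries `σ^{(g31·g22−g31−g21·g32)/γ}` and is
the exact root of the fixed-point equations (the sign of the
`g31(1−g22)` contribution differs; `x̄2` is identical under both).  Every
consumer that needs an actual equilibrium — residual checks, the
root-finding oracle cross-check, trajectory convergence references, the
bone-mass rectification — uses the self-consistent form.  Note that at
the self-consistent fixed point the canonical exponents give a
zero-trace cell block for *any* `(g31, g32)` (the fixed-point identity
`A1·x̄1^{g11−1}·x̄2^{g21}·σ^{g31} = β1` removes the tumor factor from the
diagonal), so the damped/unstable structure of the model-2 map is a
property of the as-printed reference point, not of the exact root.

A root-finding oracle (`scipy.optimize.root` on per-capita rates in log
coordinates, which enforces positivity, excludes the trivial origin, and
conditions the problem uniformly across population scales) certifies
every closed form in the test suite at 1e−6 relative tolerance.

## Stability

Jacobians are derived analytically from the implemented right-hand sides
through the coefficient form (`∂/∂D` uses the exact derivatives of
`A_i`, `B_i`, `G_ij`), never transcribed from printed matrices, and are
validated against central finite differences (relative step ≈ cbrt(eps),
tolerance 1e−6 of the flux scale) over randomized parameter sets.  The
system is block triangular (`J31 = J32 = 0`), so the spectrum is the 2×2
cell block plus `−μ/ln 10`, set exactly at `D = σ`.

Characteristic invariants are computed from the matrix itself
(`a1 = −tr J`, `a2 = Σ` principal 2×2 minors, `a3 = −det J`) and feed
the Routh–Hurwitz conditions `a1 > 0, a3 > 0, a1·a2 − a3 > 0`.  The
eigenvalue taxonomy uses a zero tolerance of `1e−9·max(1, ‖J‖)` for
analytic work and `1e−6·max(1, ‖J‖)` for coarse grid scans; marginal
points are labeled center-like, never silently stable.  Region scans
return a long-format table (one row per grid point, undefined steady
states recorded as such) suitable for region plotting.

With the canonical parameters the classification reproduces the known
structure: the base model is an exact center (zero-trace cell block);
model-1 scenarios 2, 3 and 6 are damped for σ ≤ 0.40 and scenarios 1, 4
and 8 are unstable for every σ, while scenarios 5 and 7 keep the
pure-imaginary pair for every σ (their `β̂/α̂` products leave the block
trace at zero — a consequence of the block-triangular algebra, whatever
a coarser analysis might suggest).

## Simulation

`integrate` advances `(ln x1, ln x2, D, z)` with `solve_ivp` (LSODA,
rtol 1e−8, atol 1e−10, 1-day output grid).  Integrating the cell
populations in log coordinates keeps the solver on the open positive
orthant structurally — fractional powers of negative numbers can never
arise and nothing is clamped; collapse (both populations below 1e−6 of
the reference) and blow-up are terminal events so unstable scenarios
return finite, diagnosable trajectories.  Default horizon 2000 days;
convergence studies of σ-dependent fixed points use 6000 days because
the tumor itself approaches σ with time constant `ln 10/μ ≈ 460` days
and the cells can only settle afterwards.  The bone-mass reference `x̄`
is the variant's own fixed point at `D = σ`, held constant over the run
(`reference="base"` switches to the tumor-free fixed point; for
scenarios whose fixed point depends strongly on σ this choice changes
the bone-mass trace qualitatively, e.g. scenario 3 at σ = 0.40 collapses
to deeply negative bone mass against the base reference but stays near
100% against its own).

`diagnose` applies explicit numeric rules: converged (last 10% of
samples within 1% of the fixed point), sustained oscillation (last five
peak amplitudes within 2%; peaks located by discrete-derivative sign
changes with quadratic refinement), divergent (100× the initial
envelope), collapsed (both populations below 1e−3 of the fixed point),
else undetermined.  Halving the solver tolerances moves converged final
states by far less than 0.1%.

## Randomized fixtures

`fixture_generator(seed, n, variant)` draws rates log-uniformly within a
factor of 2 of the canonical values and exponents uniformly in moderate
windows (`g11, g12 ∈ [0.5, 1.4]`, `g21 ∈ [−0.9, −0.1]`,
`g22 ∈ [−0.4, 0.4]`, couplings within ±0.3–0.4), rejecting draws with
`|γ|` (or `|Λ|`) below 1e−3, σ outside (0.01, 0.99), or fixed points
outside `[1e−6, 1e8]` cells so that every set is well conditioned for
finite differences and root finding.  The draws are deterministic per
seed.  These fixtures probe the algebra of the model family, not
biological realism: passing them certifies internal consistency
(closed forms, Jacobians, verdicts), not agreement with real bone data.

## Problem sizes and runtimes

The full test suite integrates a dozen trajectories of 2000–12000 days
and runs the randomized suites at 100 sets per variant (Jacobians), 200
per variant (oracle), and 500 random matrices (Routh–Hurwitz); it
completes in well under a minute on one CPU.  The 50×50 region scan is
2500 closed-form evaluations and eigendecompositions of 3×3 matrices.

## Known limitations

* The models are deterministic ODEs for a single remodeling unit: no
  spatial structure, no delays, no stochastic forcing, no treatment
  terms.
* Parameters are stability-calibrated abstractions, not fits to
  measured cell counts; absolute cell numbers and bone-mass percentages
  should be read comparatively.
* The scenario-2 bone-mass trace at σ = 0.05 settles at ≈ 90.1% under
  the default initial burden; the plateau is insensitive to the
  (unobservable) initial burden, as the simulation tests verify by
  comparing widely separated `D0` choices.
* Model-2 stability maps describe the as-printed reference point; at the
  self-consistent fixed point the canonical exponents always give a
  center-like cell block (see Steady states above).
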