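# Methods

This note documents the model implemented by `chondrosim`, the numerical
scheme, the default parameter and discretisation choices, and the known
limitations — in enough detail that a maintainer can judge what a passing
test suite does and does not establish.

## Model

### State variables

On the cylindrical half-plane (r, z) ∈ [0, r_max] × [0, z_max] (defaults
1.25 × 1.0 cm; z grows from the fixed base toward the impacted surface):

| symbol | meaning | units |
|---|---|---|
| C_U | healthy, unsignalled chondrocytes | cells/cm³ |
| C_T(a) | DAMP-signalled cells transitioning to catabolic | cells/cm³ |
| C_E | EPO-producing cells (recruited from C_T by ROS) | cells/cm³ |
| S_T(a) | catabolic cells, release PIC and ROS | cells/cm³ |
| S_A | EPOR-active cells, rescuable by EPO | cells/cm³ |
| D_N | necrotic cells (impact-killed), release DAMPs | cells/cm³ |
| R, M, F, P | ROS, DAMPs, PIC, EPO | nM |
| U | extracellular matrix (sulfate-equivalent) | mg/cm³ |

`a` is *state age* — how long a cell has been in its current state — not
chronological age.  The two signalled classes are age-structured
(∂_t + ∂_a transport) so that delayed transitions can be expressed through
the switch function γ(a − τ) = (γ₀/σ_w)(tanh((a − τ)/σ_w) + 1): nearly
zero below the transition age τ, rising sharply to its saturation
2γ₀/σ_w.  With the defaults (γ₀ = 1, σ_w = 0.1 d) the switch has a
half-height of 10/d and an effective width of ±0.2 d.

The switch normalisation is a genuinely open modelling choice, so it is
pluggable through `ModelParameters.gamma_form`:

* `"over_sigma"` (default) — amplitude γ₀/σ_w, saturation 20/d at the
  defaults.  A sharper switch is also a stronger one (transferred mass
  stays roughly invariant as σ_w → 0), and transitions complete within
  hours of the delay age, matching the described biology (pre-catabolic
  cells move to the EPO-producing class in 20–24 h; catabolic cells
  express the EPO receptor after an 8–12 h gap).
* `"height"` — amplitude γ₀ (saturation 2/d): transitions complete over
  days rather than hours.
* `"times_sigma"` — amplitude γ₀·σ_w (saturation 0.2/d): the κ-mediated
  transitions become negligible on a 14-day horizon and the EPO arm is
  effectively dead.

The default follows the first reading; the qualitative day-14 behaviour
discussed under *Limitations* is not sensitive to this choice.

### Dynamics

Chemicals diffuse (no-flux boundaries on all four sides), decay linearly,
and are produced by cells: ROS and PIC by the age-integrated catabolic
pool (σ_R·ΣS_T, σ_F·ΣS_T), DAMPs by necrotic cells (σ_M·D_N) and by
cytokine-mediated matrix breakdown (σ_U·U·F/(λ_F+F)), and EPO by C_E cells
under ROS drive and PIC inhibition (σ_P·C_E·R/(λ_R+R)·Λ/(Λ+F)).  All
signalling is saturating (first-order Hill factors) and the Heaviside
gates H(P_c − P) / H(P − P_c) arrest inflammatory transitions (and enable
the C_E → C_U rescue) once EPO passes its threshold P_c.  The ECM only
degrades: ∂_t U = −δ_U·U·F/(λ_F+F)·H(P_c − P); DAMP production from the
matrix term is *not* gated by EPO, mirroring the asymmetry of the
underlying model.  Cell transitions: C_U →(DAMPs) C_T →(DAMPs/PIC) S_T
→(PIC, delayed τ₁) S_A →(EPO) C_U, with the side branch C_T →(ROS, delayed
τ₂) C_E →(EPO above threshold) C_U, and apoptosis losses from S_T
(μ_ST·hill(F)·hill(M)) and S_A (μ_SA·hill(F), gated).  Apoptotic cells are
removed from the system; the solver accumulates them in per-node audit
sinks so that conservation is testable.

One intentional asymmetry is preserved from the source model: the
S_T → S_A *loss* term carries no EPO gate while the matching S_A *gain*
does.  When EPO is above threshold this removes cells from the system; the
implementation routes that mass to a dedicated `leak` audit sink.  The
configuration flag `heaviside_conservative` applies the gate on both sides
instead, making the pathway exactly conservative; it is off by default.

### Impact initial condition

The impact enters only through the initial state.  Axial strain ε (percent,
absolute value) maps to the instantly-killed fraction
Γ(ε) = clamp(0.01·p₀·(e^{K_U ε} − e^{10K_U}), 0, 1) for ε above the 10 %
viability threshold, zero below (moderate strain is not lethal).  Then
D_N(0) = Γ·ρ₀ and C_U(0) = ρ₀ − D_N(0) with ρ₀ = 100,000 cells/cm³; the
complement form keeps C_U + D_N = ρ₀ exact in floating point.  Chemicals
start at zero, U at 30 mg/cm³, and the age-structured pools empty.  Zero
strain is therefore an exact fixed point: every production term carries a
factor that is zero, and the solver reproduces it bit-for-bit over the
full horizon.

### Strain sources

* **Displacement decks.**  Three numeric columns (x, z, U2) in cm,
  comma- or whitespace-delimited, one optional header line.  Strain is the
  ratio rule ε = 100·|U2|/z; records at z ≤ 10⁻³ cm are dropped because the
  base is fixed and the ratio is ill-defined there.  Full-width decks are
  folded about the symmetry axis (mirror pairs averaged); grid nodes take
  the value of the Euclidean-nearest record, ties broken to the lowest
  record index so the lookup is deterministic.
* **Synthetic generator.**  A deterministic stand-in for the external
  finite-element impact stage: ε = ε_peak·radial(r)·depth(z) with
  radial = 1 under the indenter footprint (half-width 0.275 cm, from a
  5.5 mm indenter line) and a Gaussian tail (ℓ_r = 0.4 cm) beyond it, and
  a Gaussian depth profile centred at z_peak = 0.85 cm (ℓ_z = 0.5 cm),
  normalised so the in-domain maximum is ε_peak = 60 %.  The sub-surface
  maximum mimics the pattern such dynamic FE impact solves produce.  These
  are fixture defaults describing a plausible indenter impact, not fitted
  claims; the generator has no randomness.

What the synthetic field does *not* emulate: FE mesh noise, asymmetry of a
real impact, strain concentrations at material interfaces, or the
subchondral bone layer.  Tests that pass on it demonstrate correct model
mechanics under a smooth, idealised strain pattern — not fidelity to any
particular laboratory impact.

## Numerics

### Spatial discretisation

Cell-centred uniform grid, 51 × 41 cells by default.  Cell centring keeps
every radial node off the r = 0 axis (no coordinate-singularity special
case) and makes the finite-volume form of (1/r)∂_r(rK∂_r·) + K∂_zz·
conserve the r-weighted total exactly: the axis face carries radius zero
and the outer faces carry no flux.  The fundamental z-cosine mode decays
at the analytic rate −K(π/z_max)² up to the usual O(Δz²) correction.

### Time stepping

Each accepted step of size Δt is an operator-split composition:

1. **Chemical midpoint predictor.**  The four chemical fields are advanced
   Δt/2 by the ADI scheme below (source frozen at the step start) to give
   the concentrations the cell update will see.  This symmetrises the
   cell↔chemical coupling (second order); without it the coupling error is
   first order and dominated by the fast ROS dynamics.
2. **Cells and age cohorts.**  Every pool decays exactly:
   survived = X·e^{−LΔt} with L its total frozen loss rate; the removed
   mass X − survived is split across outgoing channels in proportion to
   their rates and credited to the destination pools.  Because arrivals
   are exactly the removals, total cells + audit sinks is invariant to
   rounding (measured drift ≲ 10⁻¹⁴ relative over 14 days).  The γ factor
   of each cohort is not frozen at the cohort midpoint but averaged
   *exactly* along the aging characteristic over [a, a+Δt] using the
   closed form of ∫tanh (log-cosh differences) — the mean of γ over the
   step a cohort actually experiences.  This matters: γ varies by O(1)
   across a step near the switch, and the frozen-midpoint variant loses an
   order of accuracy exactly where the dynamics are most interesting.
   Newborn cohorts are midpoint-corrected: born on average at Δt/2, a C_T
   newborn is exposed to half a step of the (age-independent) C_T → S_T
   channel, and the escaping mass cascades into the same step's S_T
   inflow; likewise S_T newborns see half a step of apoptosis pressure.
   The γ channels of newborns are vacuously small at age < Δt and are not
   applied.
3. **Chemicals.**  Peaceman–Rachford ADI on X_t = ∇·(K∇X) − δX + s, with
   the linear decay folded symmetrically into both implicit sweeps.  This
   is essential for ROS (δ_R = 60/d): the field is slaved to its source,
   and any scheme that splits decay from diffusion undoes in one substep
   what the other did, producing first-order error proportional to the
   field itself.  With decay inside the sweeps, the discrete
   diffusion–decay–source equilibrium is an exact fixed point of the step.
   The production source is interpolated linearly between the pre- and
   post-cell-update values, and the step is substepped so that δ·Δt_sub ≤
   0.5 per sweep (keeps the rational decay factor close to the true
   exponential).  Pure diffusion (δ = 0) conserves the r-weighted total to
   rounding and preserves constants exactly.
4. **ECM.**  Exact exponential decay at the degradation rate frozen at the
   step start.

Step size is controlled by step doubling: the result of one Δt step is
compared with two Δt/2 steps over the four chemical fields, and the
half-step result is accepted when
‖full − half‖₂ ≤ tol·‖half‖₂ + atol·√N for every chemical.  The absolute
floor atol = 10⁻⁸ nM is required because all chemicals start at exactly
zero — a purely relative test rejects every initial step.  On acceptance
the two newborn cohorts of the half steps are merged so the age grid keeps
exactly one cohort per accepted step (Δa = accepted Δt, the "natural"
age grid); the controller grows the step by safety·(tol/err)^{1/3}
(local error is O(Δt³)), capped at 2× and dt_max.  Steps are shortened to
land exactly on snapshot times.  The solver contains no randomness and
reruns are bit-identical.

Cohorts older than `a_cutoff` = 2.0 d merge into an open-ended terminal
cohort whose γ is evaluated at saturation.  Both switches (τ₁ = 0.5,
τ₂ = 1.0, σ_w = 0.1) are within ~10⁻⁹ of saturation beyond age 1.6 d, so
the lumping is exact to rounding while bounding cohort count at
a_cutoff/Δt.  The cohort decay/split kernel is JIT-compiled with numba
when available; a pure-numpy fallback with identical semantics is used
otherwise (the two differ only in floating-point summation order).

### Default discretisation and the error budget

Defaults: 51 × 41 cells, dt_init = 10⁻³ d, dt_max = 0.015 d,
tol = 5·10⁻⁵, atol = 10⁻⁸ nM.  The spatial resolution and the two time
controls were chosen together so that the discretisation-error audit
(`refinement_study`, the max over C_U, age-integrated S_T and EPO of
‖X_b − X_c‖₂/‖X_b‖₂ at day 14) lands in the intended regime: spatial
error is the dominant term of the budget, roughly 2.4·10⁻⁴ against a
halved-grid rerun, while halving the step-doubling tolerance or the age
step moves the solution by ≲ 4·10⁻⁵ — an order of magnitude less.  With a
second-order spatial scheme on the smooth default strain field the spatial
error is far below the 3 % that a coarser, first-order-dominated
configuration would show; the *ordering* (space ≫ time ≈ age) is the
property the defaults are built to exhibit.  Fine-grid fields are
restricted to the coarse grid by 2 × 2 cell-block averaging (the coarse
node is the centroid of its four fine cells, so the restriction is exact
for fields linear in r and z).

In this implementation the spatial comparison is maximised by EPO rather
than by the catabolic class: EPO and ROS have reaction–diffusion
equilibrium lengths √(K/δ) ≈ 0.04 cm, comparable to the 0.0245 cm grid
spacing, making them the hardest fields to resolve spatially (the
EPO-to-S_T error ratio ≈ 1.6 is resolution-independent from 26 × 21 to
51 × 41).  The tolerance comparison is maximised by C_U.  Only the
age-step comparison is maximised by S_T, the class most sensitive to age
resolution.

### The independent point integrator

`oracle_0d` integrates the same reaction system at a single spatial point
with a deliberately different discretisation: fixed step Δt = 5·10⁻⁴ d
equal to the age resolution, dense age slots, explicit midpoint (RK2) for
the reactions, and age transport as an exact one-slot shift after each
step.  Under a spatially uniform strain the 2-D solution must stay uniform
(no-flux boundaries) and equal the point solution; the two agree within
0.4 % on every field at day 14 (most within 0.1 %), which cross-validates
the ADI/cohort machinery against an implementation that shares only the
parameter definitions.

## Experiments

* `run_default` — the 14-day default scenario, snapshots at days 0, 1, 7,
  14, written as long-format CSV grids with solver diagnostics.
* `refinement_study` — the three-way discretisation audit described above.
* `sensitivity_scan` — one-at-a-time perturbations (28 canned values over
  β₁₁, β₁₃, λ_M, λ_F, λ_R, κ₁, κ₂, μ_DN); outputs are the day-14
  volume-integrated (2πr-weighted) totals of C_T, C_E, S_T, S_A, M, F, P,
  R and U, reported as relative changes against the default run.  No
  effect-size categories are assigned — only raw relative changes.
* `oracle_comparison` — the uniform-strain cross-check.

## Numerical choices and edge cases

* Hill factors reject negative concentrations and non-positive
  half-saturations; the ADI output is snapped to zero when rounding-level
  undershoot (< 10⁻⁹ relative to the field maximum) occurs and aborts on
  anything larger.
* The Heaviside is right-continuous (H(0) = 1), so P = P_c counts as
  "EPO at threshold reached".
* Nearest-record strain lookup is exact (KD-tree plus explicit tie
  resolution), never approximate.
* Degenerate decks (all records on the fixed base) and empty perturbation
  lists fail fast with descriptive errors.
* Step-size underflow below dt_min aborts with the time and error estimate
  in the message rather than silently accepting an inaccurate step.

## Limitations

* **The catabolic front travels outward.**  With the default parameters
  and the compact synthetic strain footprint, the top-layer catabolic
  (S_T) profile is centre-peaked and monotone decreasing in r at day 1,
  but the peak migrates outward (radial index ~18/51 by day 7, at the rim
  by day 14).  The mechanism: near the impact the cascade has high
  throughput (cells convert fast and drain fast to the EPOR-active pool
  or apoptosis), while at the rim both the inflow and — more strongly —
  the outflow saturations are tiny, so catabolic stock accumulates there,
  sustained by the ungated ECM→DAMP production which acts wherever
  cytokines are present and matrix is intact.  A consequence is that
  day-14 snapshot quantities are *past the catabolic peak* near the
  impact: accelerating the cascade (e.g. raising β₁₃ from 10 to 20)
  *lowers* the day-14 volume-integrated S_T even though it raises it at
  earlier times (e.g. day 2).  Both behaviours are confirmed by the
  independent point integrator and are insensitive to the γ
  normalisation; they are properties of the equations and parameters,
  not of the discretisation.  A strain field without compact support
  (one that loads the whole explant above the 10 % viability threshold,
  as a real finite-element impact solve may) would move the front's
  14-day position.
* Homogeneous tissue: no depth-dependent stiffness, no subchondral bone,
  no cartilage layering; the strain-to-death map is a simple exponential
  in strain magnitude.
* No pharmacological terms and no repeated/cyclic loading; the strain acts
  only through the initial condition.
* Apoptotic cells are not a state variable — they exist only as audit
  accumulators.
* The literal (non-conservative) EPO-gate variant loses cells from the
  books into the leak sink whenever EPO exceeds threshold while catabolic
  cells are still transitioning; with default parameters EPO stays well
  below threshold for 14 days, so the two variants coincide on the default
  scenario.
* First-order Lie composition underlies the step; the predictor, exact γ
  averaging and in-sweep decay raise the observable order to ~2, but no
  formal convergence proof is attempted — the refinement study is the
  empirical evidence.
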