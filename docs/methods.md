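# Methods

## Model

Each network is a linear(ised) reaction–diffusion system for deviations
`x(r, t)` from a homogeneous steady state:

```
∂x/∂t = J x + D ∇²x
```

with `J[i][j]` the first-order kinetic rate of node `j` acting on node
`i` (positive = activation, negative = inhibition; support restricted
to the network's `k` edges, diagonal cells = self-regulation) and
`D = diag(d_i)` with `d_i = 0` exactly for the non-diffusible
(cell-autonomous) nodes.  Spatial mode `q` evolves under `J − q²D`; its
growth rates are the roots of
`λ^N + a₁λ^{N−1} + ⋯ + a_N = det(λI − (J − q²D))`.

A diffusion-driven (Turing) instability requires homogeneous stability
(`q = 0`) together with growth at some `q > 0`.  On top of this textbook
criterion the screen applies two refinements that define the catalog:

**Stationary instability.**  The screen requires `a_N(q²) < 0` at some
`q² > 0`.  Because `a_N = (−1)^N det(J − q²D)`, this is exactly the
existence of a *real* positive growth rate at that wave number — a
stationary (non-oscillatory) pattern-forming mode.  Oscillatory
instabilities (a complex pair crossing through the Routh–Hurwitz
trade-off condition) are excluded from the catalog but remain visible
through `lsa.is_turing_unstable`, which implements the permissive
criterion (any root with positive real part) and reports an
`oscillatory` flag.

**Wavelength selection.**  As `q → ∞` the diffusive modes decay like
`−q²d_i` and the dominant growth tends to the spectral abscissa of the
immobile sub-block `J_NN`.  The screen requires that abscissa to be
nonpositive, so the growth maximum sits at a finite `q*` and the hit
selects a definite wavelength.  Systems whose only instability lives in
the `q → ∞` limit (an unstable immobile block acting as a local
amplifier) are excluded from the catalog by default; they can be
admitted with `ScreenOptions(wavelength_selection=False)`, in which
case a stable Jacobian with an unstable immobile block doubles as an
analytic certificate of instability for *every* positive diffusion
choice.

With both refinements in place, the three-node catalog (two diffusible
+ one immobile node, `k = 6`) reproduces the published progression
84 → 48 → 25 → 24 stable → 21 pattern-forming networks, and the
classical two-node control yields exactly the activator–inhibitor
(in-phase) and substrate-depleted (out-of-phase) designs.

## Existence sampling

Whether a topology *can* be stable or pattern-forming is an existence
question over its rate cone.  It is decided by Monte Carlo: free rate
magnitudes are drawn uniformly from (0, 0.5] (the unit-side rate box
(−0.5, 0.5) restricted to the topology's signs), diffusion coefficients
uniformly from (0, 1) under the active regime, `budget = 20,000` draws
per topology per decision, in chunks of 4,000.  Both stability and
instability conditions are invariant under joint rescaling of `(J, D)`,
so the box restricts nothing but the sampling measure.  The default
budget was chosen so that the three-node catalog counts are unchanged
when the budget is doubled (verified in the acceptance suite); a missed
witness after the full budget is a documented false-negative risk, not
a proof of impossibility.

Every topology draws from its own RNG stream derived from
`(run seed, network index, topology index)` in fixed-size chunks.
Decisions are therefore independent of which other topologies are still
active, survivors at budget `B` are a subset of survivors at any larger
budget (prefix property), and every recorded witness replays exactly.

**Stability modes.**  `stability="strict"` (default) demands strict
Routh–Hurwitz; explicit criteria for degrees 2–4, the full Routh array
for degree 5.  `stability="semistable"` additionally admits
structurally singular Jacobians — supports in which trailing
characteristic coefficients vanish identically (e.g. two nodes driven
by the same single regulator), producing exact zero eigenvalues — when
the remaining polynomial factor is strictly stable.  Engineered
production chains sit on this boundary, so the synthetic-circuit
fixture (`yeast_ip`) opts in; unconstrained catalogs use strict mode.
A positivity floor of 1e−12 on the coefficients keeps round-off on
singular supports (|noise| ≈ 1e−17) from masquerading as strict
stability.

**Instability test.**  For each stable draw, `a_N(x)` with `x = q²` is
expanded analytically in `x` (its coefficients are signed sums of
complementary minors weighted by products of the `d_i`) and evaluated
on a 32-point logarithmic grid over `x ∈ [10⁻³, 10³]`; with two
diffusible nodes the polynomial is quadratic and its interior minimum
is additionally checked in closed form, so narrow instability windows
between grid points are not missed.  A dip below −1e−12 is a hit.

## Step counting and phases

The step table counts networks and topologies per pipeline step.
Steps 1–3 count sign assignments combinatorially (`2^(free signs)` per
candidate network); step 4 counts sampled (semi)stable sign
assignments; the final step counts surviving networks together with one
topology per *distinct phase pattern* realised — the convention of the
published catalogs (each surviving three-node network realises all four
phase combinations, giving 21 × 4 = 84; the two-node control gives the
two classical designs).  Raw surviving sign assignments are also
recorded on each catalog entry.

The phase pattern of a witness is the sign vector of the real part of
the dominant eigenvector of `J − q*²D`, normalised so the first
diffusible node is positive; nodes sharing a sign are predicted in
phase.  When `q*` is the infinite-wavenumber limit (permissive mode
only) the eigenvector is evaluated at `q² = 10⁶`.  Phase constraints in
a screen veto witnesses until a matching one is found (up to 8 phase
evaluations per chunk).

## Type classification

Per network, over its surviving topologies:

* **Type III** — some *strictly* stable sampled rate set is unstable at
  every probe ratio `d₂/d₁ ∈ {0.01, 0.1, 1, 10, 100}` simultaneously
  (one rate set, all ratios: the pattern-forming conditions leave the
  diffusion coefficients unconstrained).  Strict stability is required
  so that the strongest robustness class is not certified by marginal
  (singular) witnesses.
* **Type II** — otherwise, some admissible rate set is unstable at
  equal diffusivities.
* **Type I** — otherwise (differential diffusivity required).

The hierarchy III ⊆ II-capable ⊆ capable holds by construction.  This
classification reproduces the anchored biological labels: receptor-level
Lefty inhibition gives Type II with a finite minimum diffusion ratio,
direct Lefty–Nodal inhibition gives Type III, and the engineered yeast
exemplar (whose only admissible steady states are marginal) classifies
Type II.

## Robustness

The robustness of a topology is the Monte-Carlo probability that a
uniform draw from the unit parameter box (rates in (−0.5, 0.5) under
the topology's signs, diffusion in (0, 1) under the regime) passes
stability plus instability; the binomial standard error and seed are
reported, and catalog entries carry the estimate relative to the
catalog maximum.  Strict stability is used here regardless of the
screen mode: marginal sets have zero volume.

## Minimum diffusion ratio

For two diffusible nodes, `min_diffusion_ratio` scans `d = d₂/d₁` over
a logarithmic grid (10⁻⁴…10⁴) and bisects the feasibility boundary to
1e−4.  With fully value-constrained rates the per-ratio test is
deterministic (the quadratic-dip criterion above); otherwise each ratio
runs the existence sampler.  The classical two-node Jacobian
`[[1, −1], [3, −2]]` recovers `4 + 2√3` to 1e−3.  A topology feasible at
the smallest scanned ratio reports an infimum of 0; an infeasible one
reports none.

## Simulation

The simulator uses clamped-linear kinetics: the reaction term is
`clip(Jx, −s, s)` per node with saturation `s = 1`.  This preserves the
linearisation at the origin exactly — the property the screen certifies
— while bounding the growing pattern; it makes no claim to reproduce
any particular nonlinear biochemistry, so simulated amplitudes and
far-from-onset waveforms are not biologically meaningful, only the
near-onset wavelength and phase relations are.  Integration is explicit
Euler on a regular grid with zero-flux (mirrored ghost cell) boundaries;
the diffusive CFL bound `dt ≤ h²/(2·max(D)·dims)` is enforced, with
`dt` defaulting to 80 % of it.  Defaults: 200 grid points, `h = 1`,
initial condition = steady state + uniform noise of amplitude 1e−3.
Dominant wavenumbers are read from the type-II discrete cosine
transform (the eigenbasis of the zero-flux Laplacian), mode `m`
corresponding to `q = πm/L`.  Because neighbouring modes grow at nearly
identical rates from random initial amplitudes, single-run spectral
peaks wander a few bins; the wavelength-validation tests therefore
average spectra over a small seed ensemble and stop while the dynamics
are still linear.

## Sizes used in the shipped checks

The test suite runs the full three-node catalog at budgets 20,000 and
40,000 (identical counts), the four-node catalog at a scaled budget of
2,500 draws per topology followed by re-verification of 50 randomly
drawn survivors at the default budget under independent seeds, and the
constrained Nodal/Lefty and yeast screens at the default budget.  The
full-budget four-node screen (74,240 topologies) runs in roughly a
quarter hour on one core and reproduces the same catalog; the scaled
run is the routinely exercised configuration.

## Known limitations

* Existence decisions are one-sided: sampling can prove capability but
  only bound incapability by the budget.
* Degrees above five are rejected (no general algebraic solvability);
  five-node screens are practical only with constraints, enforced by a
  configurable topology cap.
* The q²-grid bounds (10⁻³…10³ after unit-box scaling) assume the
  physically relevant instability windows are not many decades outside
  the parameter box scale; the two-diffusible-node case is exact via
  the quadratic minimum.
* Robustness compares volumes inside the chosen unit box only; it is
  not reparameterisation-invariant.
* The cycle-decomposition module labels net-positive cycles as
  destabilising candidates and net-negative as stabilising; the
  authoritative statement is which coefficients each cycle enters, and
  no closed-form inequality per cycle is asserted.
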