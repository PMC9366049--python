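# Methods

## Model and conventions

The Hedgehog burster is integrated and analyzed in **fast time**
tau = t/eps, in which the dynamics read

    dx/dtau = f(x, y) + sqrt(sigma) xi(tau),     dy/dtau = eps (x + a),

with f(x, y) = x − x³/3 − y + cos_amp · L(x) · cos(cos_freq · y) and the
logistic gate L(x) = 1/(1 + exp[gain (center − x)]).  Defaults:
eps = 1e-4, a = −0.2, cos_amp = 4, cos_freq = 40, gain = 5, center = 1.
All model constants are fields of `ModelParams` rather than literals, so
the FitzHugh–Nagumo (FHN) limit `cos_amp = 0` and parameter sweeps run
through the identical code path.

The noise convention — increments `sqrt(sigma·dt)·N(0,1)` on x per fast-time
step — is the unique one under which the frozen-y stationary density is
proportional to exp(−2U/sigma), so the Kramers formula below holds with the
stated prefactor.  All rates, mean first passage times and periods are
reported in fast-time units; in these units the deterministic bursting
cycle takes ≈ 1.4·10⁴.

The frozen-y potential is closed-form:
U(x; y) = −x²/2 + x⁴/12 + yx − cos_amp·cos(cos_freq·y)·A(x) with
A(x) = softplus(gain(x − center))/gain the exact antiderivative of L,
evaluated through `logaddexp` so every gate-related quantity is finite for
|x| up to 1e6 and beyond.  The integration constant is identically zero:
only potential differences and curvatures enter any downstream formula.

## Branch geometry

`branch_table` tabulates each stable branch of f(·, y) = 0 on a uniform y
grid (default n = 4000, ≈ 60+ points per cosine lobe) by **continuation**:
each grid point takes the stable root nearest the previous one.  This
follows the wavy right branch through its near-fold wiggles instead of
hopping onto the transient closed nullcline loops that float above it.
The barrier root used for the distance S(y) and barrier height dU(y) is
always the unstable root adjacent to the branch on the side toward the
other branch — Kramers escape is governed by the nearest saddle — which
also resolves slices with more than three roots.

The configured windows (left y ∈ [−0.66, 0.30], right y ∈ [−0.70, 0.25])
deliberately overshoot the region where a barrier exists: below y ≈ −0.667
the left branch and the barrier have merged (the system is monostable on
the right), and at y ≈ 0.2210 the right branch terminates at its upper
fold.  The tables truncate at both ends and carry a `truncated` flag; the
truncation points are the physically meaningful fold positions, and the
upper fold y ≈ 0.2210 is precisely the apex the deterministic limit cycle
carries onto the left branch (the classical starting position y₀ = 0.221).

The right branch is partitioned into **wave-lobe regions**: starts at the
local maxima of S(y) (the bottom-rightmost point of each lobe, deepest
well along the traversal), tips at the local minima of S(y) (lobe tip,
easiest escape).  On the default window this yields exactly 6 regions; in
the FHN limit (no interior extrema of S) a single region spanning the
window is returned.

## Distance matching

On each branch the accumulated mean displacement off the branch is

    lhs(y0, y) = ∫ S(u) √(|U″_m| U″_b) / (2π eps |x_b(u) + a|) · exp(−2 dU(u)/sigma) du,

the mean first passage velocity V_e = S/T_e divided by the slow speed
|dy/dtau|.  The critical transition position y* is the first downstream
solution of lhs = S(y*).  Note the sign of the exponent: the escape *rate*
enters, so the integrand carries exp(−2dU/sigma); this is what makes the
accumulated displacement finite and the lhs grow with sigma.

Numerically, the integrand is sampled on the tabulated geometry grid, the
cumulative integral is formed by trapezoid, the first sign change of
lhs − S brackets the crossing, and a bracketed root solve of the exact
(quadrature-consistent) lhs − S function polishes it; the residual
|lhs − S| at every returned y* is below 1e-8·max(1, S).

On the right branch the condition is applied lobe by lobe in increasing-y
order: the displacement integral restarts at each lobe's bottom, and if no
crossing occurs before the lobe ends the state survives into the next
lobe.  Escapes land on the left half of a lobe, before its tip — past the
tip S(y) grows much faster than the accumulated displacement.

**Starting positions.**  Defaults are y₀ = 0.221 on the left branch (the
deterministic apex) and the window bottom on the right branch; the
computed y* is insensitive to y₀ as long as y₀ is not close to y*
(shifting y₀ by ±0.05 moves y* by < 1e-4 at sigma = 0.01).  `refine_pair`
additionally iterates the pair to a fixed point in which each branch's y₀
is the other branch's y*; the refined pair equals the default-start pair
except near the collapse (below).

**The crossing.**  With default starts the left- and right-branch y*(sigma)
curves cross at (sigma_c, y_c) ≈ (0.1727, −0.249); beyond sigma_c no
complete orbit exists and staircase entries are flagged invalid.  With
refined (self-consistent) starts the two curves approach each other only
asymptotically — the finite crossing is a property of the fixed-start
procedure, and the crossing reported by `staircase` is therefore computed
from the default-start solutions while the stored curves are the refined
ones.

**Orbit, period, spikes.**  The predicted orbit glues the two slow-branch
segments between y_cl and y_cr with horizontal jumps.  The bursting
period is the slow transit time
∫ dy/(eps|x_l + a|) + ∫ dy/(eps(x_r + a)) over [y_cl, y_cr]; the
near-instantaneous jumps (O(1) fast units against O(10³–10⁴) transits) are
neglected.  Spikes per burst = wave-lobe tips traversed on the right
branch, counting the escape lobe's tip (the escape jump itself produces
the final spike).  This yields 6/5/3/1 at sigma = 0.00455/0.0207/0.0695/0.16.

**Excitable regime.**  For a ∈ [1.1, 1.5] the left branch carries a stable
rest state at x = −a and the drift factor |x_l + a| in the matching
integral vanishes there (a logarithmic divergence of the accumulated
displacement).  The threshold noise strength is defined as the smallest
sigma for which the matching condition yields a transition at least a
clearance (default 0.02 in y, about a quarter lobe) above the rest state —
escape before absorption into the slowing-down neighborhood — and located
by bisection on log sigma.  The nullcline geometry is independent of a, so
one left-branch table serves the whole sweep.  The threshold increases
monotonically with a (deeper rest state, higher barrier at the transition
window).

## Stochastic simulation and event analysis

Euler–Maruyama in fast time with dt = 5e-3 (≥ 20 steps per unit fast
relaxation time; halving dt changes no discrete outcome in the test
suite), compiled with numba; trajectories are typically recorded every
10th step (sampling interval 0.05, three orders of magnitude below a lobe
traversal time).  sigma = 0 gives deterministic forward Euler on the same
stepper for strict comparability.

**Burst segmentation** uses a hysteretic two-threshold state machine:
ON-RIGHT after x crosses above +1, ON-LEFT after x crosses below −1;
between the thresholds the previous state persists, which matters because
the wavy right branch itself dips to x ≈ 0.43 without leaving the branch.
Sojourns shorter than 1 fast unit are merged away.  Spikes are local
maxima of x with prominence ≥ 0.3 within a right sojourn, counted on a
20-fast-unit moving average: the lobe oscillation (≈ 10³ fast units, x
amplitude ≈ 2) passes unchanged while large-sigma white-noise peaks, whose
correlation time is below one fast unit, are suppressed.  Thresholds come
from the branch geometry (left branch x ≲ −1.1, right branch mostly
x ≳ 1) and are all configurable.

**Mixed-mode detection.**  Double-escape bursting means the right-branch
escape occurs at two different lobe tips across realizations.  The flag
clusters the per-burst exit positions y_cr with a quarter-lobe merge
radius and fires when ≥ 2 clusters each hold ≥ 10 % of bursts.  Spike
counts alone are deliberately not used: the left-branch entry position
also fluctuates (entering one lobe higher shaves a spike off the count)
without constituting a double escape, and at sigma = 0.0695 that entry
variability affects ≈ 20 % of bursts while every exit stays at one tip.

**Trap detection** is two-stage.  Stage 1 integrates 25 trajectories
started on the left branch at y spread over [−0.6, 0.2] for 5·10³ fast
units, discards the first half, and calls a trajectory clamped when the
central-95 % range of y over the last half is below 0.05; clamped
steady-state means are merged with radius 0.03 (under half the lobe
spacing 2π/80 ≈ 0.079, the natural trap separation).  Stage 2 confirms
each candidate with 20 restarts from its center under fresh noise; a
restart re-clamps if its median y stays within 0.1 of the center and its
95 % width stays below 0.05, and the candidate counts as a stable trap
only if ≥ 75 % of restarts re-clamp.  The vote is what separates stable
traps from the metastable transients that the model genuinely produces at
sigma = 0.5 (measured per-restart re-clamp probabilities: ≥ 0.9 for stable
traps, ≤ 0.4 for transients, so the 75 % threshold on 20 trials misclassifies
with probability ~10⁻³).  Ensemble sizes were chosen for that separation;
with them the detected counts are 3/4/6 at sigma = 0.5/0.65/0.8 and stable
across seeds.  In the FHN limit the single trap sits at the unique barrier
balance near y = 0 but its basin is wide and flat, so clustering there
should use a basin-scale merge radius (~0.1) and the trap registers as
clamped only at somewhat larger sigma (~1.3) than in the wavy model, whose
lobes pin the slow variable tightly.

## Scenario registry and reproducibility

Twelve named scenarios (S1–S4 coherent bursting, D1–D3 mixed-mode, T1–T3
traps, STAIRCASE, EXCITABLE) carry the canonical noise strengths.  Bundles
written by `run_scenario` contain CSV series, JSON reports and a manifest
(parameters, base seed, version, tolerances) from which every discrete
output (spike counts, trap counts, region indices) regenerates
bit-identically; per-trajectory seeds derive deterministically as
base + index.

## Problem sizes and numerical choices

* Branch tables: n = 4000 per branch; root polish tolerance 1e-13.
* Matching solver: trapezoid on the geometry grid + bracketed root solve,
  residual < 1e-8; refinement fixed point: tolerance 1e-6 in y, ≤ 20
  iterations; crossing bisection: relative tolerance 1e-3 in sigma.
* Simulated scenarios: 3·10⁴ fast units per seed (≈ 2–3 bursting cycles),
  5 seeds per noise strength; trap runs 5·10³ fast units per start.
* Deterministic runs converge to the limit cycle well within one cycle
  from any off-fixed-point start; statistics use complete cycles only.

## Limitations

* Kramers-rate asymptotics: the MFPT prefactor is leading-order in
  sigma/dU; agreement with direct frozen-y first-passage simulation is
  within a factor of 2 at moderate barriers (sigma = 0.8), which is the
  accuracy the distance matching inherits.  Predictions sharpen as
  sigma/dU shrinks.
* The transient closed loops of the x nullcline above the right branch are
  not continued; their dynamics are transient and excluded by the
  branch-continuation tracking.
* No weak-noise large-deviation corrections, no coupled/ensemble dynamics,
  and no prediction of mixed-mode mixture weights (these are measured
  empirically only).
* The trap census is defined relative to an observation protocol (run
  length, clamping tolerance, confirmation vote); traps are metastable on
  long enough timescales, and the reported counts are the stable set under
  that protocol.
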