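# Methods

`circumroot` simulates the growth of a single plant-root apex in 3-D as a
chain of cylindrical cross-sections whose differential elongation is
controlled by a signal-integration network. This note documents the model,
its numerical treatment and the design choices made where the design was
genuinely open.

## Growth kinematics

Only the apical elongation zone moves. It is discretized into `n`
sections of equal length; with the defaults (zone 6 D, time step
Δt = 0.1 h, baseline rate 1 D/h) `n = 60` and each section is 0.1 D long.
Every step each section elongates at the local rate and, when the rate
differs between opposite flanks, bends by

    θ = |G_left − G_right| Δt / D,

with the new material laid on a circular arc of radius
R_c = (D/2)(G_left+G_right)/(G_left−G_right), so that R_c·θ equals the mean
elongation increment exactly. The bend rotation is twist-free: the rotation
axis lies in the cross-section plane, perpendicular to the direction of
maximal growth, and the reference (φ = 0) direction is transported by the
same rotation. Sections are processed base → tip; each section's
roto-translation carries all tip-ward material rigidly. Zone extension per
step therefore equals Σ G_avr(d)·Δt to machine precision, and repeated
application of a constant bend moves a section's center on a circle of
radius exactly R_c.

After every step the apical `zone_length` of the grown curve is re-split
into `n` equal sections. Orientations are transported by spherical-linear
interpolation between the grown sections' frames, **knotted at the section
centers in arc length**: the resampled frame at a position samples the
orientation of the material now occupying it, so orientation advects with
the material (a full section per step at the zone base, fractionally at
the growth peak). This is essential: re-assigning each grid position the
frame of its containing section freezes the orientation profile in tip
coordinates and produces spurious "frozen hook" equilibria in which the
root grows sideways with a small down-pointing tip stub. Material that
leaves the zone at the base is appended to an immutable mature trace.
Frames are re-orthonormalized (Gram–Schmidt on z, y) once per resample;
without this, round-off in the determinant compounds exponentially through
the accumulated-rotation chain.

The root radius tapers over the cap as r(d) = 0.5·D·(d/d_cap)^p_cap for
d < d_cap (defaults d_cap = 1.5, p_cap = 0.4) and is 0.5 D beyond; radial
expansion over time is out of scope.

## Signal network

The elongation-rate field factorizes as G_s(t,d,φ) = G_b(d)·S_a(t,d,φ).

**Baseline zonation G_b** is a Gaussian in tip distance with
σ = 0.1·zone_length, centred on the configurable peak, and scaled so the
per-section rates sum to the baseline rate (1 D/h): with the aggregated
signal at rest the whole zone elongates at exactly the baseline rate. (A
"peak at 56 % of the elongation rate" can be quoted under other
normalizations; ours is defined by the zone-integrated rate.)

**Stimulus signals** are emitted at the tip with strength in [−1, 1],
advect along the root axis at a finite speed v with no attenuation (value
at distance d and time t is the strength emitted at t − d·D/v, linearly
interpolated between emission samples, zero before the front arrives), and
fall off linearly around the circumference from +s at the emission angle
through 0 at ±π/2 to −s at the opposite flank. Emission histories are
stored and sampled with the exact delay rather than advected on a grid, so
pulses keep their shape exactly.

**Aggregation** is a leaky (continuous-time recurrent network style)
update, S_a ← (1 − Δt/τ)·S_a + (Δt/τ)·(Σ w_i S_i + b), with linear
activation, bias b = 1 and τ = Δt by default (instantaneous response; the
Euler step is refused when Δt > τ). S_a is floored at 0: elongation rates
cannot be negative, and net inhibition beyond the bias saturates rather
than shrinking the root. The per-section kinematic inputs are G_left =
max over φ of G_s (smallest index wins ties) and G_right at the antipodal
angle. The φ grid has 361 samples over [−180°, 180°] in 3-D (duplicate
endpoints) and just the two flanks {0, π} in planar (2-D) mode.

## Gravitropism

The cap senses the angle α_g between the apex direction and gravity and
emits s_g = 2α_g/π (α_g ≤ π/2, else 1) on the top side of the root
(angle φ_g), propagating at v_g (default 5 D/h, the mid-range carrier
speed). The sensed direction is the **apex chord** — from the cross-section
at d_cap to the tip — with φ_g measured in that cross-section's frame.
Sensing the last 0.1 D section alone is degenerate: obstacle interactions
deposit permanent curl in the slowly-advecting apical material, leaving a
small tip stub aligned with gravity while the growth zone points anywhere,
and the control loop dies. When the apex is exactly aligned with gravity
the projection of "up" vanishes and the previous φ_g is kept (the strength
is zero there, so the choice is inert). A negative sensitivity w_g inverts
the response (negative gravitropism); such roots are initialized growing
upward.

## Thigmotropism

Tactile sensory points cover the root surface: 16-point rings at 8 axial
stations over the cap plus coarser rings (every 0.25 D) over the rest of
the zone, so no part of the root can sink into an obstacle unnoticed.
Contacts of the *cap* initiate the touch signal: the mean of the
intersected points gives the touch location (d_t, φ_t) and radius r_t, and
the cap taper maps it to the root-to-obstacle angle estimate
α_t = arctan(p_cap·r_t^(p_cap−1)), which diverges to π/2 at the very tip.
The signal strength is −2α_t/π, filtered by a memory with an immediate
rise and a configurable decay (τ = Δt: tracks contact exactly; τ = 10 h:
fades geometrically after contact loss). The inhibition is applied to the
flank *opposite* the contact — equivalently the touched flank is excited —
so the active response rotates the apex away from the obstacle. This is
the variant consistent with the observed phenomenology (obstacle
avoidance, a ~45° sliding angle at equal sensitivities, sliding angles
increasing with w_g, and periodic touch-release circumnutation in the
slow-decay memory regime); inhibiting the touched flank instead drives the
apex into the obstacle and anti-orders the sliding angles.

The passive response bends every section uniformly at φ_t, in quanta of
0.05° per section, until no sensory point penetrates deeper than the
tolerance (0.01 D). The smallest clearing multiple of the quantum is found
by exponential + binary search (bend composition is additive, so this is
the iterative procedure at a fraction of the cost); if 500 quanta do not
clear, the state is flagged trapped and the simulation continues with the
contact held. Bending the full chain matters: concentrating the
counter-bend near the contact deposits permanent curl in the
non-advecting apical material and destabilizes the slide. Grazing contact
within 0.005 D of a surface still counts as touch for the signal, so a
root resting on a plane keeps feeling it without triggering corrections.

## Internal oscillator

The resource-exploration oscillator emits a sinusoidal excitation at the
tip. Its phase advances as

    t_s ← t_s + Δt·T_s·(1 + sign(ΔC)/(1 + exp|ΔC|)),

where ΔC = (C(t) − C(t−Δt))/(Δt·G_avr) is the concentration change at the
tip normalized by the growth displacement (actual zone extension of the
previous step). sign(0) = 0, so a uniform field gives exactly the baseline
period P = 2π/T_s. The rate multiplier approaches 1.5 (0.5) for vanishing
positive (negative) ΔC and returns to 1 for large |ΔC|: the oscillator
responds primarily to the sign of the change. In 3-D the emission angle
rotates as φ = π + t_s with full strength; in 2-D the π offset is kept and
strength sin(t_s) is emitted on the π flank (the antisymmetric profile
expresses it on both flanks). The phase offset is load-bearing: the
opposite phasing locks roots into down-gradient travel. The emission angle
advances with the modulated oscillator time t_s (spatial and temporal
phase stay locked); a wall-clock switch is exposed.

## Quantifying circumnutation

Cycles are read off the one-side growth rate (G_s at the zonation peak,
φ = 0): local extrema with a minimum prominence of 1 % of the series range
mark the instants of maximal differential growth. Mapped to the tip
trajectory, consecutive same-type extrema give the period and each
consecutive triple gives the cycle amplitude ‖(p₁+p₃)/2 − p₂‖. The
gradient-climbing performance of a run is
f = (C(T) − C(0))/(C*(T) − C(0)) ∈ [−1, 1], where C* is the concentration
at the point reached by growing straight up-gradient at the baseline rate
for the whole run, clipped to the field bounds.

## Experiments

* **Gravitropic sweep** — horizontal start, 16 h, grid v_g ∈ {1, 5, 25}
  D/h × w_g ∈ {0.1, 0.5, 1.0}, zonation peaks 1.5 D and 3.0 D. Cycle
  amplitudes are pooled per peak group; the far/near ratio of group
  medians quantifies how a more distant growth zone amplifies the
  movements; a rank-sum test compares the pooled samples.
* **Obstacle interplay** — vertical start 2 D above a horizontal plane,
  24 h, zonation peak 1.5 D (apical actuation; with the mid-zone peak this
  implementation's slide is bounce-dominated and reproduces neither the
  45° plateau nor the sensitivity ordering). The reported angle is the
  apex direction vs the plane, averaged over contact steps after a 5 h
  settling from first contact.
* **Gradient study** — 1000 roots, 2-D, vertical start, 30 h, in a linear
  horizontal field (slope 0.05/D, clipped to [0, 1], start concentration
  0.5 so both climbing and descending are expressible). Per-root
  parameters are independent uniform draws w_s ∈ [0,1], v_s ∈ [0,10] D/h,
  T_s ∈ [0, 2π], zonation peak ∈ [0.5, 5.5] D, in that fixed order from
  one seeded generator; each simulation itself is deterministic. Only the
  oscillator parameters are randomized; the gravitropic pathway stays
  active at the package defaults (w_g = 0.5, v_g = 5 D/h). Without
  gravity's restoring pull the ensemble's lateral excursions saturate the
  performance statistic in both directions (more than a quarter of the
  roots pin f at ±1) and the group medians stop being informative; the
  oscillator-only condition is kept for the single-root exemplar runs.
* **Specialization** — four root types (crown w_g = −1, primary 0.95,
  seminal w_s = 0.95, lateral mixed; all w_t = 0.2) growing in lockstep in
  a walled box with a radial resource field peaking at the center. Other
  roots are treated as capsule chains for contact purposes. Arena size,
  seed placement and the radial-linear field form are this package's
  choices.

## What the synthetic setups do and do not show

All experiments are synthetic and noise-free: single unbranched roots,
constant diameter, homogeneous rigid obstacles, static resource fields,
no statolith physics, no mechanical elasticity, no biological variability.
Passing tests show that the stated kinematic and signal-integration rules
reproduce the study's emergent behaviors (alignment, overshoot
circumnutation, sliding, gradient climbing, specialization) under these
idealized conditions — not that real roots implement these rules.

## Numerical choices and limitations

* Δt = 0.1 h throughout; the aggregation guard refuses Δt > τ.
* Frame round-off is controlled by per-resample re-orthonormalization;
  determinants stay within 1e−12 of 1 over thousands of steps.
* Extremum detection uses a relative prominence (1 % of range), so
  arbitrarily weak but clean oscillations still count as cycles.
* The obstacle slide is a relaxation-oscillation regime: the angle series
  oscillates around its plateau, and reported angles are time averages.
* The helical reference run uses a gentle oscillator weight (0.2): at
  full weight the apex's own curling rate exceeds the emission rotation
  and the trajectory is a precessing tangle rather than a helix; even in
  the gentle regime the loop radius breathes by tens of percent (the cone
  precession is undamped), so helix checks assert the turn period and
  monotone axis advance, not circularity.
* Self-collision checking is off by default (report-only when enabled);
  trapped passive corrections are flagged and held, not resolved.
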