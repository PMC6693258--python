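# Methods

## Model

`rdscales` simulates the patterning of avian reticulate scales — the
radially symmetrical scales of the chicken footpad — as a two-species
reaction–diffusion process.  A central circular "primary placode" of
activator is seeded on an otherwise empty square domain; the claim under
test is that this primary unit subdivides into smaller secondary units that
radiate outwards sequentially around a persistent central unit.

The kinetics are the clipped-linear activator–inhibitor model of the
Kondo–Miura family.  With activator `u(x, y, t)` and inhibitor `v(x, y, t)`:

    ∂u/∂t = F(u, v) − d_u u + D_u ∇²u      F = clamp(a_u u + b_u v + c_u, 0, F_max)
    ∂v/∂t = G(u, v) − d_v v + D_v ∇²v      G = clamp(a_v u + b_v v + c_v, 0, G_max)

on `0 < x, y < L` with zero-flux (homogeneous Neumann) boundaries.
Synthesis is linear in `(u, v)` but clipped to `[0, F_max]` / `[0, G_max]`;
degradation (`−d u`) is never clipped.  The clamp form is adopted because it
is the only functional form in which all twelve tabulated constants
(`d_u, D_u, a_u, b_u, c_u, F_max, d_v, D_v, a_v, b_v, c_v, G_max`) have a
role; the caps are what bound the dynamics, since for the reference
parameter set

    d_u=0.02  D_u=0.02  a_u=0.06   b_u=−0.07  c_u=0.015   F_max=0.19
    d_v=0.031 D_v=0.4   a_v=0.0608 b_v=0.004  c_v=−0.025  G_max=0.184

the homogeneous steady state (u* ≈ 0.6785, v* ≈ 0.6020) is linearly
*unstable at k = 0* with oscillatory character (λ ≈ 0.0065 ± 0.056i): this
is not a textbook Turing regime that is stable to uniform perturbations.
Pattern selection still works because a band of stationary modes around
k ≈ 0.79 (wavelength ≈ 8 length units) grows faster (Re λ ≈ 0.0128) than
the uniform mode, and the clips cap every trajectory inside the invariant
box `0 ≤ u ≤ F_max/d_u = 9.5`, `0 ≤ v ≤ G_max/d_v ≈ 5.935`.

A practical consequence of the k = 0 instability: the uniform background
supports a stable homogeneous relaxation oscillation, and spatial
perturbations are *damped* along that limit cycle.  The system is
effectively bistable between the homogeneous oscillation and the spotted
pattern, so whether a localized seed patterns the domain depends on the
seed's strength (see *Initial conditions*).

## Numerics

* **Grid.** Cell-centred square lattice, `n × n` cells over side `L`,
  spacing `h = L/n`; cell `(i, j)` has centre `((j+0.5)h, (i+0.5)h)`.
  Default `L = 75`, `n = 75` (`h = 1`; unit spacing is the convention for
  this model family, and one cell per length unit resolves the ≈ 8-unit
  pattern wavelength with ≈ 8 cells).
* **Diffusion.** 5-point Laplacian with mirror ghost cells
  (`ghost(−1, j) = grid(0, j)` etc.), which realises the zero-flux condition
  at first order and makes the discrete integral of the Laplacian exactly
  zero — diffusion conserves mass to rounding.  The stencil is summed as
  `(N+S) + (W+E)`, which makes the update bit-exactly equivariant under
  90° rotation and reflection: a D4-symmetric initial condition keeps its
  symmetry for the whole run, to the last bit.
* **Time stepping.** Forward Euler with `dt = safety · h²/(4 max(D_u, D_v))`.
  The default `safety = 0.1` was fixed by a dt-convergence study on the
  reference run: at `safety = 0.2` the final spot count still changes when
  dt is reduced further, while `safety = 0.1` and `0.05` agree, so 0.1 is
  the largest dt at which the headline statistic is insensitive to further
  refinement.  Negative concentrations produced by
  Euler undershoot are floored to zero after each step (inactive at the
  default dt; relevant only near the stability bound).
* **Duration.** Default `t_end = 10 000` time units with snapshots every
  250; the subdivision sequence completes and the spot count is stationary
  well before this horizon.
* **Snapshots** are taken at the first completed step at or after each
  requested time, with the actual step time recorded.  Runs are fully
  deterministic; a SHA-256 fingerprint over parameters and snapshot bytes
  makes bit-identity checkable.

## Initial conditions

The reference initial condition is the circular primary placode:
`u = u0` where `(x − L/2)² + (y − L/2)² < R²` evaluated at cell centres with
strict inequality (no edge anti-aliasing), `u = 0` elsewhere, `v ≡ 0`.
Default `R = 1.5`, which covers exactly 9 cells at `h = 1`.

The spot amplitude `u0` is a free knob with default **5.0** for the
reference experiment.  The choice matters: because the homogeneous
oscillation is an attractor, a weak seed (`u0 = 1` at `R = 1.5`) is absorbed
into it and the domain ends unpatterned, while `u0 ≳ 2` nucleates the
radial subdivision sequence robustly.  5.0 sits in the middle of the
patterning range (about half the activator cap `F_max/d_u = 9.5`) and
represents a primary placode with strong, established activator expression.
Both `R` and `u0` are plain config keys, so the alternative reading of the
geometry (interpreting the tabulated 1.5 as an amplitude rather than a
radius) is a one-line config change.

Comparative generators emulate the other patterning modes discussed for
skin appendages: `initiator_row` (a row of equally spaced placodes, the
feather-tract mode), `noise` (uniform level plus seeded uniform noise, the
synchronous simultaneous-emergence mode of squamate footpads) and
`uniform` (solver testing).  All produce `t = 0` and `v ≡ 0`.

## Pattern analysis

* **Spot detection**: threshold the activator field (`u > threshold`),
  label connected components (default 8-connectivity), drop components
  below `min_area = 2` cells (single-cell numerical speckle).  The default
  threshold is the homogeneous fixed-point level `u*` ≈ 0.6785 —
  parameter-free and run-independent, since pattern peaks sit far above it
  (u ≈ 9) and troughs near zero.  One caveat is documented and accepted:
  during the initial homogeneous transient the whole background can cross
  `u*` and count as one extra domain-spanning component.
* **Subdivision time**: earliest snapshot time at which the spot count
  exceeds `max(1, count at t=0)`.
* **Radial report**: spot centroids within `central_tol = 2h` of the domain
  centre form the central unit; remaining centroid radii are sorted and
  split into rings wherever consecutive radii differ by more than
  `ring_gap = 3h`.  Within-ring coefficient of variation near zero indicates
  the radial arrangement.
* **Outcome classification** (first match wins): `homogeneous` (final
  spatial variance < 1e−6), `persistent_single_spot` (final count 1),
  `radial_subdivision` (count grew AND final field has a central unit AND
  ≥ 1 ring), else `other`.
* **Sequential radiation** is scored on the reference run by five checks:
  initial count 1; subdivision occurs; a central unit is present in ≥ 80 %
  of post-subdivision snapshots; the maximum ring radius never decreases by
  more than one cell spacing; the final count exceeds the count at
  subdivision onset.  The one-cell allowance in the monotonicity check
  exists because, after the outward wavefront completes, maturing spots
  shift their centroids by sub-cell amounts; centroid positions are only
  meaningful to grid resolution.

## Synthetic fixtures

The fixtures module renders fields with *known* structure — unions of
strict-inequality discs at a set amplitude over a low background,
optionally arranged as `k` spots equally spaced on a circle around a
central unit, or placed at random with a guaranteed minimum separation
(rejection sampling).  It shares the disc rasteriser with the
initial-condition generators, so the two cannot drift.  These fixtures
emulate the geometric structure the analyzer assumes (discrete high-`u`
units on a low background) but not the graded amplitudes, irregular spot
shapes or slow drift of solver output; analyzer tests on fixtures therefore
validate the detection and ring logic exactly, while the end-to-end checks
on real runs validate that the assumptions hold for simulated fields.

## Known limitations

* The final spot count is dt-converged but **not** h-converged: halving the
  spacing (n = 150, h = 0.5, dt/4) preserves the qualitative
  radial-subdivision outcome — subdivision, persistent central unit,
  concentric rings — but selects a different member of the family of
  near-degenerate spot arrangements (33 spots in 4 rings instead of 49 in
  5 at matched safety).  The clipped Turing dynamics amplify O(h²)
  differences in the effective dispersion relation and in the rasterised
  seed into a different deterministic trajectory.  Quantitative statements
  about exact spot counts are therefore resolution-specific; ring structure,
  spacing statistics and the outcome label are the robust observables.
* The homogeneous-oscillation/pattern bistability means outcomes for weak
  seeds depend on the seed amplitude; there is no noise in the model, so
  nothing rescues a sub-threshold seed.
* The model says nothing about real gene products; `u` and `v` are abstract
  morphogens, and no attempt is made to fit micrographs or expression
  domains.
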