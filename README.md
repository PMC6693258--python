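# rdscales

Reaction–diffusion simulation and pattern quantification for avian
reticulate-scale patterning.

Reticulate scales — the small, radially symmetrical scales covering the
ventral footpad of birds — arise from a single primary placode per pad that
is followed by rings of secondary units appearing around it.  `rdscales`
simulates this process with a clipped-linear activator–inhibitor
(Kondo–Miura type) reaction–diffusion model, seeds it with a circular
primary placode, and — rather than stopping at pictures — quantifies the
outcome: spot counts over time, the subdivision event, and the radial
"ring" statistics that make "secondary units radiate outwards sequentially
from a central unit" a testable statement.  It is aimed at developmental
biologists and modellers who want a reproducible, measurable version of
this patterning scenario, plus a harness for parameter sweeps and
comparative initial conditions (feather-tract-like initiator rows,
synchronous noisy emergence).

## Model

Activator `u` and inhibitor `v` on a square domain `0 < x, y < L` with
zero-flux boundaries:

```
∂u/∂t = F(u,v) − d_u u + D_u ∇²u     F = clamp(a_u u + b_u v + c_u, 0, F_max)
∂v/∂t = G(u,v) − d_v v + D_v ∇²v     G = clamp(a_v u + b_v v + c_v, 0, G_max)
```

Synthesis is linear but clipped; degradation is linear; the inhibitor
diffuses 20× faster than the activator (`D_v = 0.4` vs `D_u = 0.02`).
Under the reference parameters the homogeneous steady state
(`u* ≈ 0.679`, `v* ≈ 0.602`) is oscillatory-unstable even at wavenumber
zero; the pattern is contained by the synthesis caps, not by textbook
Turing conditions, and a stationary band near `k ≈ 0.79` (wavelength ≈ 8)
does the patterning.  See `docs/methods.md` for the full account.

The initial condition is the primary placode: `u = u0` inside a circle of
radius `R = 1.5` at the domain centre, `v ≡ 0`.

## Worked example

```python
import rdscales as rd

bundle = rd.run_reference()          # 75×75 domain, reference kinetics
print(bundle.label)                  # outcome classification
print(bundle.subdivision_time)       # first snapshot with count growth
print(bundle.counts[0], bundle.counts[-1])
print(bundle.reports[-1].n_rings)    # concentric rings of secondary units
```

prints

```
radial_subdivision
250.0
(0.0, 1) (10000.0, 49)
5
```

meaning: the run starts with one unit (the primary placode), the unit count
first grows at t = 250, and by t = 10 000 the stationary pattern holds 49
units arranged as a central unit surrounded by 5 concentric rings — the
radial subdivision sequence.  The same experiment is available from the
shell, along with sweeps and re-analysis of stored runs:

```
rdscales run   --out out/reference
rdscales sweep --config sweep.yaml --out out/sweep     # e.g. sweep: {D_v: [0.02, 0.4]}
rdscales analyze --run out/reference --out out/re
rdscales fixtures --out out/fixtures
```

Lowering the inhibitor diffusivity to the activator's (`D_v = 0.02`)
removes the lateral-inhibition length scale and the same experiment ends
`homogeneous` — the differential-diffusion negative control.

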