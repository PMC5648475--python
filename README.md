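# aqueflow

Quantitative cerebrospinal-fluid (CSF) dynamics in the cerebral (Sylvian)
aqueduct from cardiac-gated, three-direction phase-contrast MRI.

Ventricular enlargement occurs both in idiopathic normal pressure
hydrocephalus (iNPH) and in Alzheimer's disease (AD), and morphology alone
does not separate them. Velocity-encoded cine MRI adds physiology: from a 4D
velocity field **v**(x, t) over one cardiac cycle one can compute not just
CSF velocity but the pressure-gradient field driving it and the local
rotation (vorticity) of the flow. `aqueflow` implements that analysis chain
for researchers working with aqueductal CSF flow, together with analytic
pulsatile-flow phantoms that provide exact ground truth for every stage.

## What it computes

Phase-contrast MRI encodes velocity in signal phase, `v_d = φ_d/π · VENC_d`
per encoding direction (head–foot, right–left, anterior–posterior). From
the decoded field the incompressible Navier–Stokes momentum balance is
solved pointwise for the pressure gradient

```
∇p = μ∇²v − ρ ∂v/∂t − ρ (v·∇)v        [Pa/m]
```

(viscosity − acceleration − convection; ρ = 1000 kg/m³ and μ = 1.0×10⁻³
Pa·s for CSF by default), and rotation as the curl ∇×v (reported in rad/s
and cycles/s). All derivatives are 2nd-order central differences, periodic
over the cardiac cycle in time; voxels without a full difference stencil
inside the CSF lumen are excluded rather than estimated one-sidedly.

Around that core:

- **`phantoms`** — Womersley pulsatile tube flow (with cardiac harmonics),
  Poiseuille and rigid-rotation test fields, an MR phase-encoding model
  with VENC wrap, complex Gaussian noise and partial-volume averaging, and a
  study-scale cohort simulator (19 controls / 10 iNPH / 7 AD).
- **`velocimetry`** — VENC scaling, aliasing detection, periodic temporal
  phase unwrapping.
- **`segmentation`** — spatially regularized fuzzy c-means
  (`SpatialFuzzyCMeans`, sklearn-style) to delineate the CSF lumen despite
  partial-volume mixing.
- **`roi`** — entry/outlet ROI contracts (4–8 pixels for velocity and
  pressure gradient, 12–20 for rotation) and per-subject scalar metrics.
- **`stats`** — two-sided Mann–Whitney U and two-sample Kolmogorov–Smirnov
  tests (exact by enumeration at small samples), Tukey box-plot summaries
  with outside/far-out classification.
- **`pipeline` / `cli`** — a reproducible, manifest-logged orchestration of
  the whole chain (`aqueflow simulate | velocimetry | segment | fields |
  metrics | stats | run-all`).

## Worked example

Recover the driving pressure gradient of a Womersley phantom (2 mm tube
radius, 60 bpm, 32 cardiac phases, 0.5 mm voxels, amplitude 100 Pa/m):

```python
import numpy as np
from aqueflow import WomersleyPhantomSpec, womersley_velocity, pressure_gradient

spec = WomersleyPhantomSpec(
    tube_radius=2.0, heart_rate=60.0, n_cardiac_phases=32,
    voxel_size=0.5, grid_shape=(24, 24, 10),
    pressure_gradient_amplitude=100.0,
)
field, truth = womersley_velocity(spec)      # truth: dp/dz(t) in Pa/m
gp, terms = pressure_gradient(field)
recovered = gp.values[gp.valid][:, :, 2].mean(axis=0)  # mean axial dp/dz per phase
amp = 0.5 * (recovered.max() - recovered.min())
print(f"alpha = {spec.womersley_number:.2f}")
print(f"recovered amplitude = {amp:.1f} Pa/m  (true 100.0)")
print(f"relative error = {abs(amp - 100) / 100:.3f}")
```

prints

```
alpha = 5.01
recovered amplitude = 101.8 Pa/m  (true 100.0)
relative error = 0.018
```

i.e. at a Womersley number of 5 — oscillatory flow with a thin viscous
boundary layer, as in the aqueduct — the voxelwise Navier–Stokes evaluation
recovers the driving gradient to within 2%.

A full study emulation (36 subjects, three groups, both statistical tests,
box-plot summaries and a reproducibility manifest):

```sh
aqueflow run-all --out results/cohort --seed 1
```

which reports, per metric, the three pairwise comparisons and whether the
run reproduces the qualitative separation pattern (pressure gradient and
rotation elevated in patients at matched velocity).

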