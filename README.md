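# nanodent

Desk-scale molecular-dynamics nanoindentation of crystals, with Oliver-Pharr
modulus extraction, deformation-method elastic tensors, per-particle strain
maps, and an interaction-feature regression of the Young's modulus.

Instrumented nanoindentation measures the directional Young's modulus *E* of
a crystal face from the unloading branch of a force-displacement curve.
Simulating the experiment atomistically — a spherical tip driven into a
crystal slab at constant velocity, held, then retracted — makes the same
measurement on a computer and exposes everything the instrument hides: the
atomic displacement field, the plastic zone under the tip, and the
sensitivity of the reported modulus to crystal size, unloading rate, and
indent density.  `nanodent` implements that workflow end to end at a scale
that runs on one CPU in minutes, for method development, teaching, and
testing analysis pipelines against known ground truths.

## The model

- **Indentation.**  A repulsive spherical tip (force K(R−r)² inside the
  contact) advances into a laterally periodic slab whose bottom layers are
  frozen, in a displacement-controlled load → hold → unload schedule under a
  Langevin bath (velocity-Verlet/BAOAB, LJ + cutoff Coulomb + bonded terms).
- **Oliver-Pharr.**  The unloading branch is fitted to P = α(h−h_f)^m; with
  S = dP/dh|_{h_max}, h_c = h_max − ε P_max/S (ε = 0.75), and the spherical
  area A_c = π(2Rh_c − h_c²):

      E_r = (√π / 2β) · S / √A_c ,   1/E_r = (1−ν_s²)/E + (1−ν_i²)/E_i .

- **Elastic tensors.**  Small strains (±0.004…0.012, engineering shear
  convention) applied to a periodic bulk cell; NVT-averaged virial stresses
  give the 6×6 stiffness C by Hooke's-law regression, and the compliance
  projects to the face modulus E(hkl) = 1/(n_i n_j n_k n_l S_ijkl).
- **Strain fields.**  Per-particle deformation gradients from neighbor least
  squares; von Mises local shear invariant η_vm of the Green-Lagrange strain
  maps the plastic zone.
- **Interaction features.**  Geometric hydrogen-bond detection, residence
  times, and indentation-axis-projected features (x_A, x_B, x_C) feeding an
  affine model E = β₀ + β₁x_A + β₂x_B + β₃x_C.

## Worked example

```python
import numpy as np
from nanodent import (make_toy_crystal, add_vacuum_and_template,
                      Indenter, run_indentation, analyze_curve)
from nanodent.indentation import block_average
from nanodent.sweeps import desk_protocol

slab, ff = make_toy_crystal("lj_fcc", (7, 7, 7), seed=0, temperature=24.0)
slab = add_vacuum_and_template(slab, vacuum_height=4.0, template_layers=2)
tip = Indenter(radius=1.5, center=np.zeros(3))
curve, snaps = run_indentation(slab, ff, tip, desk_protocol(max_depth=0.6, seed=0))
res = analyze_curve(block_average(curve, 50), radius=1.5, nu_sample=0.30)
print(f"S = {res.fit.stiffness:.0f} kJ/mol/nm^2, m = {res.fit.m:.2f}")
print(f"h_c = {res.h_c:.3f} nm, A_c = {res.a_c:.2f} nm^2")
print(f"E_r = {res.e_reduced:.2f} GPa, E = {res.e_sample:.2f} GPa")
```

prints

```
S = 4888 kJ/mol/nm^2, m = 2.89
h_c = 0.438 nm, A_c = 3.53 nm^2
E_r = 3.83 GPa, E = 3.48 GPa
```

— the tip meets the surface, the 1372-atom argon-like crystal yields under
~0.6 nm of penetration, and the unloading slope translates through the
contact area into a reduced modulus of ~4 GPa, the same scale as the
crystal's bulk C11 of 4.1 GPa from the independent stress-strain route:

```python
from nanodent import make_toy_crystal, measure_strain_samples, estimate_stiffness
bulk, ff = make_toy_crystal("lj_fcc", (4, 4, 4))
C = estimate_stiffness(measure_strain_samples(bulk, ff, temperature=0.0))
print(np.round(C.c[:3, :3], 2))   # GPa
# [[4.13 2.36 2.36]
#  [2.36 4.13 2.36]
#  [2.36 2.36 4.13]]
```

The same steps are available as a CLI: `nanodent build / indent / fit /
elastic / project / strain / features / predict / sweep / mae`.

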