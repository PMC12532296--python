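# Methods

`nanodent` reproduces, at desk scale, the simulation methodology used to
predict Young's moduli of molecular crystals by virtual nanoindentation:
a molecular-dynamics slab is indented by a displacement-controlled spherical
tip, the force-displacement curve is analyzed with the Oliver-Pharr method,
and two complementary routes (stress-strain elastic tensors with directional
projection, and an interaction-feature regression) estimate the same
quantity from bulk and structural information.  This note records the model,
its assumptions, the defaults, and the choices made where the design was
genuinely open.

## Units

Internal units are nm, ps, u (g/mol) and kJ/mol, the standard MD set.
Derived: force kJ/mol/nm, velocity nm/ps (1 nm/ps = 1000 m/s), stress
kJ/mol/nm^3 with 1 kJ mol^-1 nm^-3 = 1.66054 MPa.  Laboratory indentation
rates quoted in m/s convert exactly (8.3 m/s = 0.0083 nm/ps).

## Crystal slabs and boundary conditions

Slabs are built by replicating an explicit-atom orthogonal unit cell
(non-orthogonal cells are rejected with the offending components named; no
space-group expansion is attempted).  `add_vacuum_and_template` opens the
box along z with a vacuum gap and freezes the bottom crystallographic
layers.  Freezing the crystal's own bottom layers is mechanically equivalent
to mounting it on a rigid support template and avoids introducing a second
species; the number of frozen layers (default 2) is a modeling choice, since
the thickness of a real support's grip is not a well-defined quantity.
Layers are identified by clustering z coordinates with a 0.05 nm gap
threshold — robust for flat orthogonal slabs, unreliable for rough or
reconstructed surfaces (known limitation).  x and y are periodic with
minimum-image wrapping; z is open in slab geometry and periodic in the bulk
cells used for the deformation route.

## Force field and engine

Interactions are truncated, energy-shifted Lennard-Jones pairs plus optional
cutoff Coulomb (shifted potential; no Ewald — a deliberate desk-scale
simplification documented as a deviation from production practice) and
harmonic bonds/angles.  Integration is velocity Verlet with a local Langevin
thermostat in the BAOAB splitting; friction 0 recovers NVE exactly.  Frozen
particles never move and are excluded from the thermostat, the temperature,
and the kinetic stress.  The default timestep is 2 fs; the Lennard-Jones
sweeps use 8 fs, about tau/270 for the argon-like parameters
(epsilon = 1 kJ/mol, sigma = 0.34 nm, m = 40 u), verified by an NVE drift
below 1e-5 over 5,000 steps.  Virial stress is reported tension-positive:
sigma = -(1/V)[sum m v v^T + sum r_ij f_ij^T + bonded terms], so a
thermalized ideal gas shows hydrostatic pressure +n k_B T/V and a compressed
crystal a negative trace.  For slabs, V is footprint times crystal thickness
(z extent plus one mean interlayer spacing); for bulk cells, the box volume.

Neighbor handling is a cell-binned Verlet list (0.2 nm skin, displacement
rebuild criterion).  The indentation hot path runs entirely inside a
compiled kernel; all paths are deterministic for a given seed.

## Toy presets

Three generators stand in for real organic crystals:

- `lj_fcc` — argon-like fcc crystal.  The lattice constant is obtained by
  minimizing the truncated-potential lattice energy (0.5269 nm at 0 K,
  slightly below the untruncated 2^(1/6) sqrt(2) sigma), and, when a bath
  temperature is given, re-equilibrated to zero pressure at that temperature
  by a secant iteration on short NVT runs (0.5325 nm at 24 K).  Without this
  thermal correction a warm slab carries compressive lateral stress and
  slowly extrudes toward the vacuum, contaminating slow-unloading
  measurements.
- `diatomic_molecular` — bonded two-site molecules on a cubic lattice, used
  to exercise bonded terms and molecule-resolved bookkeeping.
- `hbonded_lattice` — one donor-H...acceptor motif per cell at ideal
  geometry (0.28 nm, linear) with a tunable tilt from the z axis, used to
  test hydrogen-bond detection and the directional features.

These fixtures share the topology and energetics *types* of molecular
crystals but none of their anisotropy, polymorphism or long-range
electrostatics; a passing suite demonstrates the machinery, not transferable
accuracy for any real compound.

## Indentation protocol

The analytic repulsive sphere (force K (R - r)^2 inside the contact,
K = 2000 kJ/mol/nm^3 by default) is the default tip; a rigid atomistic-like
LJ wall is available but no specific tip material is parameterized, since
none is defined unambiguously at this scale.  Depth zero is the mean z of
the topmost layer at the start of loading, which averages out thermal
roughness.  The schedule is equilibrate, load at constant velocity, hold
(thermostatted, so the contact can settle), unload.  The curve records the
tip reaction force every step; fits operate on non-overlapping 50-sample
block means with the raw curve retained.

Desk-scale defaults (`desk_protocol`): load at 0.08 nm/ps to 0.45-0.6 nm
depth with a 1.5 nm tip, hold 8 ps, unload at 0.04 nm/ps, bath 24 K
(0.2 epsilon/k_B) with friction 5 ps^-1.  The strong friction stands in for
the internal dissipation channels (phonon baths, molecular relaxations) that
a few-thousand-atom crystal lacks, and carries the viscoelastic rate
sensitivity of the contact; these conditions were calibrated once, during
development, so that the contact operates in the regime where the
experimental parameter effects are observable, and then verified on seed
triples disjoint from those used during calibration.  Rates are roughly 10^3
faster than laboratory practice in proportion to the ~10^3-fold smaller
crystal; sweep comparisons are between rates, never against absolute
laboratory values.

## Oliver-Pharr analysis

The unloading branch is fitted to P = alpha (h - h_f)^m by bounded
least squares (multistart over h_f to avoid the well-known local-minimum
trap), over samples whose force lies in the 25-95 % window of the force at
the start of unloading.  The residual depth is constrained non-negative by
default — a physical indent cannot end below the undeformed surface — which
also suppresses a spurious high-exponent basin on noisy thermal curves; the
bound is a parameter for users fitting exotic curves.  S = dP/dh is
evaluated analytically at the depth where unloading starts.  Contact depth
h_c = h_max - 0.75 P_max/S (epsilon = 0.75, the spherical/paraboloid value);
area A_c = pi (2 R h_c - h_c^2), the true spherical cap function rather than
the paraboloid pi R h_c (on a sphere this choice biases the Hertz round trip
by only ~h/8R, verified at 0.5 % for h = 0.04 R); E_r = sqrt(pi)/(2 beta) *
S/sqrt(A_c) with beta = 1; and E = (1 - nu^2) E_r for the rigid tip
(nu = 0.30 by default, the value commonly assumed for molecular crystals).
An elastic-tip correction accepts user-supplied (E_i, nu_i).

## Elastic tensors and projection

The deformation route uses a fully periodic bulk supercell.  Each Voigt
component is strained at 0.004, 0.008 and 0.012 (engineering shear
convention, gamma = 2 eps_ij, stated in every I/O header), in both signs by
default — the sign pair cancels odd-order anharmonic bias; positive-only
mode exists for literal replication of positive-strain protocols.  Stresses
are NVT averages over the second half of each run, or single static
evaluations at temperature zero (the athermal limit, appropriate for
0 K constants; for the Bravais-lattice fcc toy no internal relaxation
exists, so the static route is exact).  Sheared periodic cells are handled
with a general-cell minimum image (brute-force pair loop — the bulk cells
are small).  Columns of C come from through-origin least squares of
delta sigma versus strain; C is symmetrized with the asymmetry norm kept,
and non-positive-definite results are flagged rather than rejected.

The directional modulus is E(n) = 1/(n_i n_j n_k n_l S_ijkl), with the
Voigt-to-full compliance mapping carrying factors 1, 2, 4 on
normal/mixed/shear entries — the classic factor-2 trap is covered by a
round-trip test.  Face normals come from the reciprocal lattice,
n ~ h a* + k b* + l c*; (hkl) and (-h-k-l) give identical moduli.
Externally computed tensors (e.g. from quantum-chemical calculations) are
accepted through the CSV reader for projection-only workflows; the reader
refuses files that do not declare units and the shear convention.

On the LJ fcc toy at 0 K the stress-strain tensor agrees with an independent
finite-difference energy-density oracle to 0.1 % and obeys the Cauchy
relation C12 = C44 expected for central pair potentials.

## Atomic strain fields

Per-particle deformation gradients follow the neighbor-least-squares scheme
standard in atomistic visualization tools: F_i = (sum d d0^T)(sum d0 d0^T)^-1
over reference neighbors within 1.4 times the first-neighbor distance
(captures the first shell robustly under deformation; the analysis tool's
own cutoff in the original workflow is not published).  Green-Lagrange
strain eta = (F^T F - I)/2 and the von Mises local shear invariant
eta_vm = sqrt(eta_yz^2 + eta_xz^2 + eta_xy^2 + [(eta_xx - eta_yy)^2 +
(eta_xx - eta_zz)^2 + (eta_yy - eta_zz)^2]/6) are rotation-invariant by
construction.  Particles with fewer than three non-coplanar reference
neighbors are flagged undefined, never zero-filled.  The residual imprint is
reported as a topmost-particle height grid (0.25 nm bins) differenced
before/after indentation — the same information as a triangulated surface
mesh, in a simpler, directly testable form.

## Interaction features and regression

Hydrogen bonds use the standard geometric criterion (donor-acceptor
distance <= 0.35 nm, donor-H...acceptor angle >= 135 deg; both
configurable).  Residence times use the continuous-survival definition (an
unbroken presence run; re-formation starts a new event), the simplest
defensible reading; an intermittent variant can be built from the presence
masks, which are exposed.  The directional features are this package's own
operational constructions: x_A = hydrogen bonds per particle weighted by
|cos| of the bond axis to the indentation direction, x_B = the analogous
stacking term on declared ring-centroid species, x_C = mean residence time
in ps.  The shipped `paper_fig3` coefficient preset
(151.4, -31252.9, -561637.2, -8.26) reproduces a published five-crystal fit
for formula-fidelity evaluation; those coefficients are only meaningful
with their original (unpublished) feature definitions, so refitting on one's
own feature table via OLS — with R^2 and standardized importance
|beta| sd(x) reported — is the supported workflow.

## Parameter sweeps

Three drivers replicate the experiment-design sweeps with replicate seeds
and n-1 standard errors:

- **Unloading rate** (0.08, 0.016, 0.0032 nm/ps on a 7x7x7-cell slab,
  0.6 nm depth): the modulus falls monotonically as unloading slows
  (3.45 -> 2.49 GPa at seed 1), because the viscoelastic contact carries a
  velocity-proportional force component that stiffens fast retraction.
- **Crystal size** (N0 = 7x7x4 cells vs 2N0 with doubled depth): the
  smaller crystal reads stiffer (2.92 vs 2.83 GPa at seed 1); the tip's
  elastic field senses the rigid frozen base through the thin crystal.
  The lateral-doubling member of the size family (4N0) is generated and
  swept but not used as the acceptance trend: at fixed tip radius, doubling
  the footprint also doubles the spacing ratio, so at desk scale the pure
  size effect is confounded with the (opposite-signed, larger) spacing
  effect, and the net direction is seed-noise dominated.  At production
  scale the two softening effects align and the confound is immaterial.
- **Indenter spacing** (tip radius 0.9 vs 1.8 nm in a fixed 8x8x6-cell box,
  i.e. spacing ratios 2.37 vs 1.18): the modulus rises strongly as the
  spacing ratio falls (1.83 -> 3.38 GPa at seed 1), the periodic tip array
  interacting through the shared stress field.

All three directions match the reported behaviour of the full-scale
simulations.  Because each point is a 3-seed mean of a stochastic
measurement with ~0.1-0.2 GPa standard error, individual orderings are
statistical statements; the chosen contrasts were verified stable across
three disjoint seed triples.

## Numerical and degenerate-input policy

Pair forces refuse configurations with particles closer than 0.01 nm (force
blow-up guard); integration aborts on non-finite forces with the step index;
strained cells refuse |strain| > 0.02 (outside the stated elastic regime);
readers refuse files without unit/convention headers; sweeps record failed
runs and continue, reporting partial failure in the exit status.  All
randomness flows from explicit seeds; identical seeds give bit-identical
trajectories, curves and sweep tables.

## Known limitations

- No Ewald electrostatics, constraints, barostat, or atomistic tip
  chemistry; no hardness extraction or tip-area calibration.
- Layer detection assumes flat layers; rough surfaces merge.
- The toy crystals cannot reproduce absolute moduli, anisotropies, or the
  plasticity mechanisms (slip planes, dislocation networks) of real
  molecular crystals; sweep results demonstrate directions, not magnitudes.
- The published regression coefficients cannot be re-derived from this
  package's features, by construction (their feature definitions are not
  public); only the formula and the refitting machinery are reproducible.
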