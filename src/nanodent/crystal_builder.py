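"""Construction of crystal slabs for indentation and bulk deformation runs.

A slab is built by replicating an explicit-atom unit cell, optionally opening
the box along z with a vacuum gap and freezing the bottom crystallographic
layers (the rigid support that in a laboratory setup would be a dense template
under the crystal).  Toy presets with known mechanical properties serve as
test fixtures standing in for real organic crystals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "UnitCell",
    "Box",
    "CrystalSlab",
    "ForceField",
    "build_supercell",
    "add_vacuum_and_template",
    "make_toy_crystal",
    "layer_indices",
    "TOY_PRESETS",
]

#: particles closer than this at construction time indicate a malformed cell
MIN_SEPARATION = 0.05  # nm

#: gap in z used to split a slab into crystallographic layers
LAYER_GAP = 0.05  # nm


@dataclass
class UnitCell:
    """Explicit-atom unit cell: lattice vectors (rows, nm) plus a basis.

    ``bonds`` are optional intra-cell harmonic-bond pairs; each entry is
    ``(i, j, (ox, oy, oz))`` where the image offset says which periodic copy
    of atom ``j`` the bond reaches.
    """

    lattice_vectors: np.ndarray
    species: list[str]
    frac_coords: np.ndarray
    charges: np.ndarray
    masses: np.ndarray
    bonds: Optional[list[tuple[int, int, tuple[int, int, int]]]] = None

    def __post_init__(self) -> None:
        self.lattice_vectors = np.asarray(self.lattice_vectors, dtype=float)
        self.frac_coords = np.asarray(self.frac_coords, dtype=float) % 1.0
        self.charges = np.asarray(self.charges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.lattice_vectors.shape != (3, 3):
            raise ValueError("lattice_vectors must be 3x3")
        vol = np.linalg.det(self.lattice_vectors)
        if vol <= 0:
            raise ValueError(f"lattice vectors must span positive volume, got {vol:g}")
        n = len(self.species)
        if self.frac_coords.shape != (n, 3):
            raise ValueError("frac_coords shape mismatch with species")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        if self.bonds:
            for i, j, _ in self.bonds:
                if not (0 <= i < n and 0 <= j < n):
                    raise ValueError(f"bond ({i},{j}) references invalid atom index")

    @property
    def n_atoms(self) -> int:
        return len(self.species)


@dataclass
class Box:
    """Orthogonal simulation box; x/y are periodic, z may be open (slab)."""

    lengths: np.ndarray  # (3,) nm
    pbc: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.any(self.lengths <= 0):
            raise ValueError("box lengths must be positive")

    @property
    def footprint_area(self) -> float:
        return float(self.lengths[0] * self.lengths[1])


@dataclass
class CrystalSlab:
    """Particle state of a slab: positions/velocities plus static metadata.

    ``reference_positions`` freeze the as-built configuration for later
    displacement and atomic-strain analysis.  ``frozen_mask`` marks template
    particles that never move.
    """

    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    charges: np.ndarray
    masses: np.ndarray
    box: Box
    frozen_mask: np.ndarray
    reference_positions: np.ndarray
    bonds: Optional[np.ndarray] = None  # (nb, 2) int
    angles: Optional[np.ndarray] = None  # (na, 3) int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        self.species = np.asarray(self.species)
        self.charges = np.asarray(self.charges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.frozen_mask = np.asarray(self.frozen_mask, dtype=bool)
        self.reference_positions = np.ascontiguousarray(
            self.reference_positions, dtype=float
        )
        n = self.n_particles
        for name in ("velocities", "reference_positions"):
            if getattr(self, name).shape != (n, 3):
                raise ValueError(f"{name} shape mismatch")
        if np.any(np.abs(self.velocities[self.frozen_mask]) > 0):
            raise ValueError("frozen particles must have zero velocity")

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def copy(self) -> "CrystalSlab":
        return CrystalSlab(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            species=self.species.copy(),
            charges=self.charges.copy(),
            masses=self.masses.copy(),
            box=Box(self.box.lengths.copy(), self.box.pbc),
            frozen_mask=self.frozen_mask.copy(),
            reference_positions=self.reference_positions.copy(),
            bonds=None if self.bonds is None else self.bonds.copy(),
            angles=None if self.angles is None else self.angles.copy(),
            metadata=dict(self.metadata),
        )


@dataclass
class ForceField:
    """Generic pairwise + bonded force field.

    pair:   {(species_a, species_b): (epsilon kJ/mol, sigma nm)}; symmetric.
    bonds:  {(species_a, species_b): (k kJ/mol/nm^2, r0 nm)} harmonic terms.
    angles: {(a, b, c): (k kJ/mol/rad^2, theta0 rad)} harmonic angle terms.
    Hydrogen-bond donor/acceptor species labels are carried here so that
    interaction-feature analysis needs no extra input file.
    """

    pair: dict
    cutoff: float
    coulomb: bool = False
    permittivity: float = 1.0
    bonds: dict = field(default_factory=dict)
    angles: dict = field(default_factory=dict)
    donors: list[str] = field(default_factory=list)
    hydrogens: list[str] = field(default_factory=list)
    acceptors: list[str] = field(default_factory=list)
    aromatic: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        for key, (eps, sig) in list(self.pair.items()):
            if eps < 0 or sig <= 0:
                raise ValueError(f"invalid LJ parameters for {key}: {(eps, sig)}")

    def pair_params(self, s1: str, s2: str) -> tuple[float, float]:
        """LJ parameters for a species pair, Lorentz-Berthelot if absent."""
        if (s1, s2) in self.pair:
            return self.pair[(s1, s2)]
        if (s2, s1) in self.pair:
            return self.pair[(s2, s1)]
        e1, g1 = self.pair[(s1, s1)]
        e2, g2 = self.pair[(s2, s2)]
        return (float(np.sqrt(e1 * e2)), 0.5 * (g1 + g2))

    def validate_for_box(self, box: Box) -> None:
        lim = 0.5 * min(box.lengths[0], box.lengths[1])
        if self.cutoff >= lim:
            raise ValueError(
                f"cutoff {self.cutoff:g} nm must be < half the smallest lateral "
                f"box length ({lim:g} nm)"
            )


def _check_orthogonal(lattice: np.ndarray) -> np.ndarray:
    """Return diagonal lengths, or raise naming the offending components."""
    off = []
    for i in range(3):
        for j in range(3):
            if i != j and abs(lattice[i, j]) > 1e-9 * max(1.0, abs(lattice[i, i])):
                off.append((i, j, lattice[i, j]))
    if off:
        desc = ", ".join(f"a[{i}][{j}]={v:g}" for i, j, v in off)
        raise ValueError(
            "orthogonal simulation box requested but the lattice has non-zero "
            f"off-diagonal components: {desc}"
        )
    return np.diag(lattice).copy()


def _min_separation(positions: np.ndarray, box: Box) -> float:
    """Smallest pair distance with lateral minimum image (brute via KD-tree)."""
    if len(positions) < 2:
        return np.inf
    pos = positions.copy()
    lx, ly, lz = box.lengths
    pos[:, 0] %= lx
    pos[:, 1] %= ly
    # pad z so the periodic KD-tree never wraps the open direction
    zspan = 2.0 * (abs(pos[:, 2]).max() + 1.0)
    shift = pos[:, 2].min()
    pos[:, 2] -= shift
    boxsize = [lx, ly, max(zspan, lz * 4)]
    if box.pbc[2]:
        pos[:, 2] = (pos[:, 2] + shift) % lz
        boxsize[2] = lz
    tree = cKDTree(pos, boxsize=boxsize)
    d, _ = tree.query(pos, k=2)
    return float(d[:, 1].min())


def build_supercell(cell: UnitCell, reps: Sequence[int]) -> CrystalSlab:
    """Replicate a unit cell into a fully periodic orthogonal supercell.

    The result is bulk-periodic in all three directions; use
    :func:`add_vacuum_and_template` to turn it into an indentation slab.
    """
    reps = tuple(int(r) for r in reps)
    if any(r < 1 for r in reps):
        raise ValueError(f"reps must be >= 1 in every direction, got {reps}")
    diag = _check_orthogonal(cell.lattice_vectors)
    n = cell.n_atoms
    base = cell.frac_coords * diag  # Cartesian within one cell

    shifts = np.array(
        [(i, j, k) for i in range(reps[0]) for j in range(reps[1]) for k in range(reps[2])],
        dtype=float,
    )
    ncells = len(shifts)
    positions = (shifts[:, None, :] * diag + base[None, :, :]).reshape(-1, 3)
    species = np.tile(np.asarray(cell.species), ncells)
    charges = np.tile(cell.charges, ncells)
    masses = np.tile(cell.masses, ncells)
    box = Box(diag * np.asarray(reps, dtype=float), pbc=(True, True, True))

    bonds = None
    if cell.bonds:
        blist = []
        cell_of = {
            (int(s[0]), int(s[1]), int(s[2])): ci for ci, s in enumerate(shifts)
        }
        for ci, (cx, cy, cz) in enumerate(shifts.astype(int)):
            for i, j, (ox, oy, oz) in cell.bonds:
                tgt = (
                    (cx + ox) % reps[0],
                    (cy + oy) % reps[1],
                    (cz + oz) % reps[2],
                )
                blist.append((ci * n + i, cell_of[tgt] * n + j))
        bonds = np.asarray(blist, dtype=np.int64)

    slab = CrystalSlab(
        positions=positions,
        velocities=np.zeros_like(positions),
        species=species,
        charges=charges,
        masses=masses,
        box=box,
        frozen_mask=np.zeros(len(positions), dtype=bool),
        reference_positions=positions.copy(),
        bonds=bonds,
        metadata={"reps": reps, "cell_diag_nm": diag.tolist()},
    )
    dmin = _min_separation(positions, box)
    if dmin < MIN_SEPARATION:
        raise ValueError(
            f"construction produced particles {dmin:.4f} nm apart "
            f"(< {MIN_SEPARATION} nm): malformed unit cell"
        )
    return slab


def layer_indices(slab: CrystalSlab, gap: float = LAYER_GAP) -> list[np.ndarray]:
    """Split particles into crystallographic layers by clustering z with a gap.

    Robust for orthogonal slabs with flat layers; rough surfaces may merge
    layers (documented limitation).
    """
    z = slab.positions[:, 2]
    order = np.argsort(z)
    zs = z[order]
    breaks = np.nonzero(np.diff(zs) > gap)[0]
    return [np.sort(part) for part in np.split(order, breaks + 1)]


def add_vacuum_and_template(
    slab: CrystalSlab, vacuum_height: float, template_layers: int = 2
) -> CrystalSlab:
    """Open the box along z and freeze the bottom crystallographic layers.

    The frozen layers play the role of the rigid support template that holds
    the crystal during indentation; their particles keep their positions and
    get zero velocity.
    """
    if vacuum_height <= 0:
        raise ValueError("vacuum_height must be positive")
    if template_layers < 1:
        raise ValueError("template_layers must be >= 1")
    out = slab.copy()
    layers = layer_indices(out)
    if template_layers >= len(layers):
        raise ValueError(
            f"template_layers={template_layers} would freeze all {len(layers)} "
            "layers: nothing left to indent"
        )
    frozen = np.concatenate(layers[:template_layers])
    out.frozen_mask[frozen] = True
    out.velocities[frozen] = 0.0
    top = out.positions[:, 2].max()
    out.box = Box(
        np.array([out.box.lengths[0], out.box.lengths[1], top + vacuum_height]),
        pbc=(True, True, False),
    )
    out.metadata["template_layers"] = int(template_layers)
    out.metadata["vacuum_height_nm"] = float(vacuum_height)
    return out


# ---------------------------------------------------------------------------
# toy presets


def _lj_fcc_cell(a: float, eps: float, sigma: float, mass: float) -> UnitCell:
    frac = np.array(
        [[0.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]]
    )
    return UnitCell(
        lattice_vectors=np.eye(3) * a,
        species=["Ar"] * 4,
        frac_coords=frac,
        charges=np.zeros(4),
        masses=np.full(4, mass),
    )


def _optimize_fcc_lattice_constant(eps: float, sigma: float, cutoff: float) -> float:
    """0 K lattice constant of the truncated-shifted LJ fcc crystal.

    Minimizes the periodic lattice energy per particle over the cubic lattice
    constant; with a 2.5 sigma cutoff the optimum sits slightly below the
    untruncated value a = 2^(1/6) * sqrt(2) * sigma.
    """
    from scipy.optimize import minimize_scalar

    from .md_engine import compute_forces

    def energy_per_atom(a: float) -> float:
        cell = _lj_fcc_cell(a, eps, sigma, 1.0)
        reps = max(4, int(np.ceil(2.0 * cutoff / a)) + 1)
        slab = build_supercell(cell, (reps, reps, reps))
        ff = ForceField(pair={("Ar", "Ar"): (eps, sigma)}, cutoff=cutoff)
        _, epot = compute_forces(slab, ff)
        return epot / slab.n_particles

    a0 = 2 ** (1 / 6) * np.sqrt(2) * sigma
    res = minimize_scalar(
        energy_per_atom, bounds=(0.9 * a0, 1.05 * a0), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


_LJ_EPS, _LJ_SIGMA, _LJ_MASS = 1.0, 0.34, 40.0  # argon-like
_LJ_CUTOFF = 2.5 * _LJ_SIGMA
_fcc_a_cache: dict = {}


def _thermal_fcc_lattice_constant(a0: float, temperature: float) -> float:
    """Zero-pressure lattice constant at finite T by secant on the NVT pressure.

    A slab built at the 0 K constant but simulated warm carries compressive
    lateral stress (the box blocks thermal expansion) and slowly extrudes
    upward, which biases indentation observables; presets therefore
    equilibrate the lattice constant to the requested bath temperature.
    """
    from .md_engine import Thermostat, run_nvt

    cell = _lj_fcc_cell(a0, _LJ_EPS, _LJ_SIGMA, _LJ_MASS)
    ff = ForceField(pair={("Ar", "Ar"): (_LJ_EPS, _LJ_SIGMA)}, cutoff=_LJ_CUTOFF)

    def pressure(scale: float) -> float:
        slab = build_supercell(cell, (4, 4, 4))
        slab.positions *= scale
        slab.box.lengths = slab.box.lengths * scale
        slab.reference_positions = slab.positions.copy()
        _, _, log = run_nvt(
            slab, ff, duration=3.0, dt=0.008,
            thermostat=Thermostat(temperature, 5.0), seed=1234, log_stride=10,
        )
        tail = log.iloc[len(log) // 2:]
        return -float(
            (tail["sigma_xx"] + tail["sigma_yy"] + tail["sigma_zz"]).mean() / 3.0
        )

    s0, s1 = 1.0, 1.01
    p0, p1 = pressure(s0), pressure(s1)
    for _ in range(4):
        if abs(p1 - p0) < 1e-9:
            break
        s2 = s1 - p1 * (s1 - s0) / (p1 - p0)
        s2 = min(max(s2, 0.98), 1.06)
        s0, p0, s1 = s1, p1, s2
        p1 = pressure(s1)
        if abs(p1) < 20.0:  # MPa
            break
    return a0 * s1


def _make_lj_fcc(reps, rng, temperature: float = 0.0) -> tuple[CrystalSlab, ForceField]:
    key = (_LJ_EPS, _LJ_SIGMA, _LJ_CUTOFF)
    if key not in _fcc_a_cache:
        _fcc_a_cache[key] = _optimize_fcc_lattice_constant(*key)
    a = _fcc_a_cache[key]
    if temperature > 0.0:
        tkey = key + (round(float(temperature), 1),)
        if tkey not in _fcc_a_cache:
            _fcc_a_cache[tkey] = _thermal_fcc_lattice_constant(a, temperature)
        a = _fcc_a_cache[tkey]
    cell = _lj_fcc_cell(a, _LJ_EPS, _LJ_SIGMA, _LJ_MASS)
    slab = build_supercell(cell, reps)
    ff = ForceField(pair={("Ar", "Ar"): (_LJ_EPS, _LJ_SIGMA)}, cutoff=_LJ_CUTOFF)
    slab.metadata.update(preset="lj_fcc", lattice_constant_nm=a,
                         epsilon_kj_mol=_LJ_EPS, sigma_nm=_LJ_SIGMA,
                         build_temperature_K=float(temperature))
    return slab, ff


def _make_diatomic(reps, rng) -> tuple[CrystalSlab, ForceField]:
    a, d = 0.62, 0.15
    frac = np.array([[0.5, 0.5, 0.5 - d / (2 * a)], [0.5, 0.5, 0.5 + d / (2 * a)]])
    cell = UnitCell(
        lattice_vectors=np.eye(3) * a,
        species=["A", "B"],
        frac_coords=frac,
        charges=np.array([-0.1, 0.1]),
        masses=np.array([14.0, 14.0]),
        bonds=[(0, 1, (0, 0, 0))],
    )
    slab = build_supercell(cell, reps)
    # deterministic sub-picometre jitter breaks exact lattice symmetry
    slab.positions += rng.normal(0.0, 1e-4, slab.positions.shape)
    slab.reference_positions = slab.positions.copy()
    ff = ForceField(
        pair={("A", "A"): (0.5, 0.32), ("B", "B"): (0.5, 0.32)},
        cutoff=0.9,
        coulomb=True,
        bonds={("A", "B"): (40000.0, d)},
    )
    slab.metadata.update(preset="diatomic_molecular")
    return slab, ff


def _make_hbonded(reps, rng, orientation_deg: float = 0.0) -> tuple[CrystalSlab, ForceField]:
    """Lattice of donor-H...acceptor motifs with a tunable tilt from z.

    Each cell carries one O_d-H group and one acceptor O_a placed so that the
    donor-acceptor axis makes ``orientation_deg`` with the z axis (tilt in the
    x-z plane); ideal geometry (linear, 0.28 nm) so every motif satisfies the
    default geometric hydrogen-bond criterion.
    """
    a = 0.55
    th = np.radians(orientation_deg)
    u = np.array([np.sin(th), 0.0, np.cos(th)])
    center = np.full(3, a / 2)
    r_da, r_oh = 0.28, 0.10
    pos = np.array([center - u * r_da / 2,            # donor O
                    center - u * (r_da / 2 - r_oh),   # H on the donor, toward A
                    center + u * r_da / 2])           # acceptor O
    cell = UnitCell(
        lattice_vectors=np.eye(3) * a,
        species=["OD", "HD", "OA"],
        frac_coords=pos / a,
        charges=np.array([-0.4, 0.4, 0.0]),
        masses=np.array([16.0, 1.0, 16.0]),
        bonds=[(0, 1, (0, 0, 0))],
    )
    slab = build_supercell(cell, reps)
    ff = ForceField(
        pair={
            ("OD", "OD"): (0.6, 0.30),
            ("OA", "OA"): (0.6, 0.30),
            ("HD", "HD"): (0.05, 0.10),
        },
        cutoff=0.8,
        coulomb=True,
        bonds={("OD", "HD"): (40000.0, r_oh)},
        donors=["OD"],
        hydrogens=["HD"],
        acceptors=["OA"],
    )
    slab.metadata.update(preset="hbonded_lattice", orientation_deg=float(orientation_deg))
    return slab, ff


TOY_PRESETS = {
    "lj_fcc": _make_lj_fcc,
    "diatomic_molecular": _make_diatomic,
    "hbonded_lattice": _make_hbonded,
}


def make_toy_crystal(
    preset: str, reps: Sequence[int], seed: int = 0, **kwargs
) -> tuple[CrystalSlab, ForceField]:
    """Build a named toy crystal and its matching force field.

    Presets: ``lj_fcc`` (Lennard-Jones fcc at its 0 K lattice constant),
    ``diatomic_molecular`` (bonded two-site molecules on a cubic lattice),
    ``hbonded_lattice`` (donor-H...acceptor motifs at a tunable tilt, keyword
    ``orientation_deg``).  Deterministic given ``seed``.
    """
    if preset not in TOY_PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; available: {sorted(TOY_PRESETS)}"
        )
    rng = np.random.default_rng(seed)
    return TOY_PRESETS[preset](tuple(int(r) for r in reps), rng, **kwargs)
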