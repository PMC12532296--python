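"""Deformation-method elastic constants and directional Young's moduli.

A fully periodic bulk supercell is subjected to small uniaxial and shear
strains; the NVT-averaged (or, at 0 K, static) virial stress response gives
the 6x6 Voigt stiffness through generalized Hooke's law, column by column.
The compliance tensor projected along a crystallographic face normal yields
the directional Young's modulus E(hkl) = 1 / (n_i n_j n_k n_l S_ijkl).

Engineering (Voigt) shear convention throughout: gamma = 2 eps_ij; the
off-diagonal entries of the applied strain matrix carry gamma / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .crystal_builder import CrystalSlab, ForceField
from .md_engine import _CompiledFF, Thermostat
from .units import KB, KJ_MOL_NM3_TO_GPA

__all__ = [
    "ElasticTensor",
    "StrainSample",
    "voigt_strain_matrix",
    "apply_strain",
    "measure_strain_samples",
    "estimate_stiffness",
    "directional_modulus",
    "face_normal",
    "isotropic_stiffness",
]

MAX_STRAIN = 0.02  # engineering strain bound of the elastic regime


# ---------------------------------------------------------------------------
# triclinic force evaluation (sheared periodic boxes)


@njit(cache=True, fastmath=True)
def _forces_triclinic(pos, hmat, hinv, tidx, eps4, sigsq, ushift, q, qfac, rc,
                      bi, bj, bk, br0, forces):
    """Brute-force pairs with general-cell minimum image; returns (epot, virial)."""
    n = pos.shape[0]
    epot = 0.0
    vir = np.zeros((3, 3))
    rc2 = rc * rc
    nb = bi.shape[0]
    bonded = np.zeros((n, 8), np.int64) - 1
    bcount = np.zeros(n, np.int64)
    for b in range(nb):
        i = bi[b]
        j = bj[b]
        if bcount[i] < 8:
            bonded[i, bcount[i]] = j
            bcount[i] += 1
        if bcount[j] < 8:
            bonded[j, bcount[j]] = i
            bcount[j] += 1
    for i in range(n - 1):
        for j in range(i + 1, n):
            skip = False
            for b in range(bcount[i]):
                if bonded[i, b] == j:
                    skip = True
                    break
            if skip:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            sx = hinv[0, 0] * dx + hinv[0, 1] * dy + hinv[0, 2] * dz
            sy = hinv[1, 0] * dx + hinv[1, 1] * dy + hinv[1, 2] * dz
            sz = hinv[2, 0] * dx + hinv[2, 1] * dy + hinv[2, 2] * dz
            sx -= np.rint(sx)
            sy -= np.rint(sy)
            sz -= np.rint(sz)
            dx = hmat[0, 0] * sx + hmat[0, 1] * sy + hmat[0, 2] * sz
            dy = hmat[1, 0] * sx + hmat[1, 1] * sy + hmat[1, 2] * sz
            dz = hmat[2, 0] * sx + hmat[2, 1] * sy + hmat[2, 2] * sz
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2:
                continue
            ti = tidx[i]
            tj = tidx[j]
            s2 = sigsq[ti, tj] / r2
            s6 = s2 * s2 * s2
            e4 = eps4[ti, tj]
            epot += e4 * (s6 * s6 - s6) - ushift[ti, tj]
            fr = 6.0 * e4 * (2.0 * s6 * s6 - s6) / r2
            if qfac != 0.0:
                qq = qfac * q[i] * q[j]
                if qq != 0.0:
                    r = np.sqrt(r2)
                    epot += qq * (1.0 / r - 1.0 / rc)
                    fr += qq / (r2 * r)
            fx = fr * dx
            fy = fr * dy
            fz = fr * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
            vir[0, 0] += dx * fx
            vir[0, 1] += dx * fy
            vir[0, 2] += dx * fz
            vir[1, 0] += dy * fx
            vir[1, 1] += dy * fy
            vir[1, 2] += dy * fz
            vir[2, 0] += dz * fx
            vir[2, 1] += dz * fy
            vir[2, 2] += dz * fz
    for b in range(nb):
        i = bi[b]
        j = bj[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        sx = hinv[0, 0] * dx + hinv[0, 1] * dy + hinv[0, 2] * dz
        sy = hinv[1, 0] * dx + hinv[1, 1] * dy + hinv[1, 2] * dz
        sz = hinv[2, 0] * dx + hinv[2, 1] * dy + hinv[2, 2] * dz
        sx -= np.rint(sx)
        sy -= np.rint(sy)
        sz -= np.rint(sz)
        dx = hmat[0, 0] * sx + hmat[0, 1] * sy + hmat[0, 2] * sz
        dy = hmat[1, 0] * sx + hmat[1, 1] * sy + hmat[1, 2] * sz
        dz = hmat[2, 0] * sx + hmat[2, 1] * sy + hmat[2, 2] * sz
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - br0[b]
        epot += 0.5 * bk[b] * dr * dr
        fr = -bk[b] * dr / r
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        vir[0, 0] += dx * fx
        vir[0, 1] += dx * fy
        vir[0, 2] += dx * fz
        vir[1, 0] += dy * fx
        vir[1, 1] += dy * fy
        vir[1, 2] += dy * fz
        vir[2, 0] += dz * fx
        vir[2, 1] += dz * fy
        vir[2, 2] += dz * fz
    return epot, vir


class _PeriodicSystem:
    """Bulk-periodic system with a general (possibly sheared) cell matrix."""

    def __init__(self, slab: CrystalSlab, ff: ForceField, hmat: Optional[np.ndarray] = None):
        if not all(slab.box.pbc):
            raise ValueError("deformation route requires a fully periodic bulk cell")
        self.cff = _CompiledFF(slab, ff)
        self.positions = slab.positions.copy()
        self.masses = slab.masses.copy()
        self.hmat = np.diag(slab.box.lengths) if hmat is None else np.asarray(hmat, float)
        self.hinv = np.linalg.inv(self.hmat)

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.hmat)))

    def forces_energy_virial(self):
        forces = np.zeros_like(self.positions)
        c = self.cff
        epot, vir = _forces_triclinic(
            self.positions, self.hmat, self.hinv, c.tidx, c.eps4, c.sigsq,
            c.ushift, c.charges, c.qfac, c.cutoff,
            c.bond_i, c.bond_j, c.bond_k, c.bond_r0, forces,
        )
        return forces, epot, vir

    def stress_gpa(self, velocities: Optional[np.ndarray] = None) -> np.ndarray:
        """Instantaneous virial stress, GPa, tension positive."""
        _, _, vir = self.forces_energy_virial()
        kin = np.zeros((3, 3))
        if velocities is not None:
            kin = (self.masses[:, None, None]
                   * velocities[:, :, None] * velocities[:, None, :]).sum(axis=0)
        s = -(kin + vir) / self.volume * KJ_MOL_NM3_TO_GPA
        return 0.5 * (s + s.T)


# ---------------------------------------------------------------------------
# strain bookkeeping


def voigt_strain_matrix(component: int, magnitude: float) -> np.ndarray:
    """Symmetric strain matrix for Voigt component 1..6 (engineering shear).

    Components 1-3 are the normal strains xx, yy, zz; 4-6 the shears yz, xz,
    xy with off-diagonal entries magnitude / 2.
    """
    if component not in range(1, 7):
        raise ValueError("Voigt component must be in 1..6")
    e = np.zeros((3, 3))
    if component <= 3:
        e[component - 1, component - 1] = magnitude
    else:
        pairs = {4: (1, 2), 5: (0, 2), 6: (0, 1)}
        i, j = pairs[component]
        e[i, j] = e[j, i] = magnitude / 2.0
    return e


def apply_strain(slab: CrystalSlab, component: int, magnitude: float) -> CrystalSlab:
    """Affine deformation x -> (I + eps) x of a fully periodic bulk cell.

    The deformed cell matrix is stored in ``metadata['box_matrix']`` (the box
    becomes triclinic under shear); lengths keep the diagonal for reference.
    Refuses strains outside the stated elastic regime (|magnitude| > 0.02).
    """
    if abs(magnitude) > MAX_STRAIN:
        raise ValueError(
            f"|strain| = {abs(magnitude):g} exceeds the elastic-regime bound "
            f"{MAX_STRAIN}"
        )
    if not all(slab.box.pbc):
        raise ValueError("apply_strain requires a fully periodic bulk cell")
    eps = voigt_strain_matrix(component, magnitude)
    fmat = np.eye(3) + eps
    out = slab.copy()
    out.positions = slab.positions @ fmat.T
    out.reference_positions = out.positions.copy()
    h0 = slab.metadata.get("box_matrix")
    h0 = np.diag(slab.box.lengths) if h0 is None else np.asarray(h0, float)
    h1 = fmat @ h0
    out.box.lengths = np.abs(np.diag(h1))
    out.metadata["box_matrix"] = h1
    out.metadata["applied_strain"] = (int(component), float(magnitude))
    return out


@dataclass
class StrainSample:
    """Stress response of one strained configuration."""

    component: int  # Voigt 1..6
    magnitude: float  # signed engineering strain
    stress: np.ndarray  # mean stress, Voigt 6-vector, GPa
    reference_stress: np.ndarray  # unstrained mean stress, GPa
    stress_se: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if abs(self.magnitude) > MAX_STRAIN:
            raise ValueError("strain magnitude outside elastic regime")
        self.stress = np.asarray(self.stress, float)
        self.reference_stress = np.asarray(self.reference_stress, float)
        if not np.isfinite(self.stress).all():
            raise ValueError("non-finite stress in sample")

    @property
    def delta_stress(self) -> np.ndarray:
        return self.stress - self.reference_stress


def _voigt6(s: np.ndarray) -> np.ndarray:
    return np.array([s[0, 0], s[1, 1], s[2, 2], s[1, 2], s[0, 2], s[0, 1]])


def _mean_stress(slab, ff, temperature, duration, dt, seed, equil_fraction=0.5):
    """Time-averaged stress of a (possibly sheared) bulk cell, GPa.

    ``temperature == 0`` evaluates the static lattice (no dynamics), the
    appropriate limit for athermal elastic constants.
    """
    hmat = slab.metadata.get("box_matrix")
    sys_ = _PeriodicSystem(slab, ff, hmat)
    if temperature <= 0:
        return _voigt6(sys_.stress_gpa()), np.zeros(6)
    rng = np.random.default_rng(seed)
    n = len(sys_.positions)
    masses = sys_.masses[:, None]
    v = rng.normal(size=(n, 3)) * np.sqrt(KB * temperature / masses)
    v -= v.mean(axis=0)
    gamma = 2.0  # ps^-1, stiff coupling for short sampling runs
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    forces, _, _ = sys_.forces_energy_virial()
    n_steps = int(round(duration / dt))
    n_skip = int(n_steps * equil_fraction)
    acc = []
    for s in range(n_steps):
        v += 0.5 * dt * forces / masses
        sys_.positions += 0.5 * dt * v
        v = c1 * v + c2 * np.sqrt(KB * temperature / masses) * rng.normal(size=v.shape)
        sys_.positions += 0.5 * dt * v
        forces, _, _ = sys_.forces_energy_virial()
        v += 0.5 * dt * forces / masses
        if s >= n_skip:
            acc.append(_voigt6(sys_.stress_gpa(v)))
    acc = np.array(acc)
    return acc.mean(axis=0), acc.std(axis=0, ddof=1) / np.sqrt(len(acc))


def measure_strain_samples(
    slab: CrystalSlab,
    ff: ForceField,
    magnitudes: Sequence[float] = (0.004, 0.008, 0.012),
    components: Sequence[int] = (1, 2, 3, 4, 5, 6),
    temperature: float = 0.0,
    duration: float = 2.0,
    dt: float = 0.004,
    seed: int = 0,
    both_signs: bool = True,
) -> list[StrainSample]:
    """Strain the bulk cell component by component and average its stress.

    Both strain signs are applied by default (cancels odd-order anharmonic
    bias); pass ``both_signs=False`` for the literal positive-only protocol.
    """
    ref_stress, _ = _mean_stress(slab, ff, temperature, duration, dt, seed)
    samples = []
    sub = 1
    for comp in components:
        for mag in magnitudes:
            signs = (1.0, -1.0) if both_signs else (1.0,)
            for sg in signs:
                strained = apply_strain(slab, comp, sg * mag)
                stress, se = _mean_stress(
                    strained, ff, temperature, duration, dt, seed + 7919 * sub
                )
                samples.append(
                    StrainSample(comp, sg * mag, stress, ref_stress, se)
                )
                sub += 1
    return samples


# ---------------------------------------------------------------------------
# stiffness estimation and projection


@dataclass
class ElasticTensor:
    """6x6 Voigt stiffness (GPa) with compliance on demand."""

    c: np.ndarray
    provenance: dict = field(default_factory=dict)
    asymmetry: float = 0.0
    positive_definite: bool = True
    _s: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        c = np.asarray(self.c, float)
        if c.shape != (6, 6):
            raise ValueError("stiffness must be 6x6")
        sym = 0.5 * (c + c.T)
        denom = max(np.linalg.norm(c), 1e-300)
        self.asymmetry = float(np.linalg.norm(c - c.T) / denom)
        self.c = sym
        eig = np.linalg.eigvalsh(sym)
        self.positive_definite = bool(eig.min() > 0)

    @property
    def s(self) -> np.ndarray:
        """Compliance, GPa^-1 (lazy inverse)."""
        if self._s is None:
            try:
                self._s = np.linalg.inv(self.c)
            except np.linalg.LinAlgError as err:
                raise ValueError("singular stiffness tensor") from err
        return self._s


def isotropic_stiffness(c11: float, c12: float, c44: Optional[float] = None) -> ElasticTensor:
    """Isotropic (or cubic, if c44 given) stiffness from its two/three constants."""
    if c44 is None:
        c44 = 0.5 * (c11 - c12)
    c = np.zeros((6, 6))
    c[:3, :3] = c12
    np.fill_diagonal(c[:3, :3], c11)
    c[3, 3] = c[4, 4] = c[5, 5] = c44
    return ElasticTensor(c, {"method": "analytic"})


def estimate_stiffness(samples: Sequence[StrainSample]) -> ElasticTensor:
    """Hooke's-law regression of stress responses, column by column.

    For each strained Voigt component j, the column C(:, j) is the
    through-origin least-squares slope of delta sigma versus the signed
    engineering strain across magnitudes.  The result is symmetrized with the
    asymmetry norm reported; a non-positive-definite outcome is flagged, not
    silently accepted.
    """
    by_comp: dict[int, list[StrainSample]] = {}
    for s in samples:
        by_comp.setdefault(s.component, []).append(s)
    missing = [j for j in range(1, 7) if j not in by_comp]
    if missing:
        raise ValueError(f"missing strain samples for Voigt components {missing}")
    c = np.zeros((6, 6))
    for j, group in by_comp.items():
        eps = np.array([g.magnitude for g in group])
        dsig = np.array([g.delta_stress for g in group])  # (k, 6)
        c[:, j - 1] = eps @ dsig / (eps @ eps)
    tensor = ElasticTensor(
        c,
        provenance={
            "method": "stress-strain deformation",
            "magnitudes": sorted({abs(s.magnitude) for s in samples}),
        },
    )
    return tensor


_VOIGT_IDX = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]


def compliance_tensor(tensor: ElasticTensor) -> np.ndarray:
    """Full s_ijkl from the Voigt compliance, with factors 1 / 2 / 4."""
    s4 = np.zeros((3, 3, 3, 3))
    sv = tensor.s
    for a, (i, j) in enumerate(_VOIGT_IDX):
        for b, (k, l) in enumerate(_VOIGT_IDX):
            factor = 1.0
            if a >= 3:
                factor *= 2.0
            if b >= 3:
                factor *= 2.0
            val = sv[a, b] / factor
            for ii, jj in ((i, j), (j, i)):
                for kk, ll in ((k, l), (l, k)):
                    s4[ii, jj, kk, ll] = val
    return s4


def directional_modulus(tensor: ElasticTensor, direction: np.ndarray) -> float:
    """Young's modulus along a unit direction: E(n) = 1 / (n n n n : s).

    E(n) = E(-n) by construction.  The direction must be normalized.
    """
    n = np.asarray(direction, float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-8:
        raise ValueError("direction must be a unit vector")
    if not tensor.positive_definite:
        raise ValueError("stiffness tensor is not positive definite")
    s4 = compliance_tensor(tensor)
    comp = np.einsum("i,j,k,l,ijkl->", n, n, n, n, s4)
    return float(1.0 / comp)


def face_normal(cell, hkl: Sequence[int]) -> np.ndarray:
    """Unit normal of the (hkl) plane from the cell's reciprocal vectors."""
    h, k, l = (int(x) for x in hkl)
    if h == 0 and k == 0 and l == 0:
        raise ValueError("(000) does not define a plane")
    a = np.asarray(cell.lattice_vectors, float)
    recip = np.linalg.inv(a).T  # rows: a*, b*, c* (2 pi omitted)
    n = h * recip[0] + k * recip[1] + l * recip[2]
    return n / np.linalg.norm(n)
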