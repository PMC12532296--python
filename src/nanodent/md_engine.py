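"""Minimal molecular-dynamics engine for slab geometries.

Lennard-Jones + cutoff Coulomb pair forces, harmonic bonds and angles,
velocity-Verlet integration with a local Langevin thermostat (BAOAB
splitting), virial stress, and trajectory/scalar logging.  Lateral (x, y)
directions are periodic with the minimum-image convention; z is periodic only
for bulk deformation boxes.  Frozen particles never move and are excluded
from the thermostat, the temperature, and the kinetic stress.

Pair interactions use a truncated, energy-shifted potential so the energy is
continuous at the cutoff; Coulomb uses the same shifted-potential scheme
(an Ewald sum is deliberately out of scope at desk scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .crystal_builder import Box, CrystalSlab, ForceField, layer_indices
from .units import COULOMB_CONSTANT, KB, KJ_MOL_NM3_TO_MPA

__all__ = [
    "Thermostat",
    "EngineState",
    "StressTensor",
    "Integrator",
    "compute_forces",
    "step",
    "run_nvt",
    "virial_stress",
    "minimize_slab",
]

_OVERLAP_LIMIT = 0.01  # nm; below this pair forces blow up


@dataclass
class Thermostat:
    """Langevin thermostat; ``friction=0`` disables it (NVE)."""

    target_temperature: float = 300.0  # K
    friction: float = 1.0  # ps^-1


@dataclass
class StressTensor:
    """Symmetric 3x3 stress in MPa, tension positive, with its decomposition."""

    total: np.ndarray
    kinetic: np.ndarray
    virial: np.ndarray

    @property
    def pressure(self) -> float:
        """Hydrostatic pressure in MPa (positive = compression)."""
        return float(-np.trace(self.total) / 3.0)

    def voigt(self) -> np.ndarray:
        """(xx, yy, zz, yz, xz, xy) in MPa."""
        s = self.total
        return np.array([s[0, 0], s[1, 1], s[2, 2], s[1, 2], s[0, 2], s[0, 1]])


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _build_pairs(pos, lx, ly, pbcz, lz, rlist):
    """Half pair list within rlist, linked-cell binning, lateral periodicity."""
    n = pos.shape[0]
    ncx = max(int(lx / rlist), 1)
    ncy = max(int(ly / rlist), 1)
    zmin = pos[:, 2].min()
    zspan = pos[:, 2].max() - zmin + 1e-9
    if pbcz:
        zmin = 0.0
        zspan = lz
    ncz = max(int(zspan / rlist), 1)
    small = ncx < 3 or ncy < 3 or (pbcz and ncz < 3)
    if small:
        cap = n * (n - 1) // 2
        pi = np.empty(cap, np.int64)
        pj = np.empty(cap, np.int64)
        m = 0
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                dx -= lx * np.rint(dx / lx)
                dy -= ly * np.rint(dy / ly)
                if pbcz:
                    dz -= lz * np.rint(dz / lz)
                if dx * dx + dy * dy + dz * dz < rlist * rlist:
                    pi[m] = i
                    pj[m] = j
                    m += 1
        return pi[:m], pj[:m]

    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, np.int64)
    nxt = np.full(n, -1, np.int64)
    cidx = np.empty(n, np.int64)
    for i in range(n):
        cx = int((pos[i, 0] % lx) / lx * ncx) % ncx
        cy = int((pos[i, 1] % ly) / ly * ncy) % ncy
        if pbcz:
            cz = int((pos[i, 2] % lz) / lz * ncz) % ncz
        else:
            cz = int((pos[i, 2] - zmin) / zspan * ncz)
            if cz >= ncz:
                cz = ncz - 1
            if cz < 0:
                cz = 0
        c = (cz * ncy + cy) * ncx + cx
        cidx[i] = c
        nxt[i] = head[c]
        head[c] = i

    cap = max(64, int(n * 90))
    pi = np.empty(cap, np.int64)
    pj = np.empty(cap, np.int64)
    m = 0
    r2max = rlist * rlist
    for cz in range(ncz):
        for cy in range(ncy):
            for cx in range(ncx):
                c = (cz * ncy + cy) * ncx + cx
                i = head[c]
                while i >= 0:
                    for ozi in range(-1, 2):
                        z2 = cz + ozi
                        if pbcz:
                            z2 = z2 % ncz
                        elif z2 < 0 or z2 >= ncz:
                            continue
                        for oyi in range(-1, 2):
                            y2 = (cy + oyi) % ncy
                            for oxi in range(-1, 2):
                                x2 = (cx + oxi) % ncx
                                c2 = (z2 * ncy + y2) * ncx + x2
                                j = head[c2]
                                while j >= 0:
                                    if j > i:
                                        dx = pos[i, 0] - pos[j, 0]
                                        dy = pos[i, 1] - pos[j, 1]
                                        dz = pos[i, 2] - pos[j, 2]
                                        dx -= lx * np.rint(dx / lx)
                                        dy -= ly * np.rint(dy / ly)
                                        if pbcz:
                                            dz -= lz * np.rint(dz / lz)
                                        if dx * dx + dy * dy + dz * dz < r2max:
                                            if m >= cap:
                                                return pi[:0], pj[:0]
                                            pi[m] = i
                                            pj[m] = j
                                            m += 1
                                    j = nxt[j]
                    i = nxt[i]
    return pi[:m], pj[:m]


@njit(cache=True, fastmath=True)
def _pair_forces(pos, pi, pj, tidx, eps4, sigsq, ushift, q, qfac, rc,
                 lx, ly, pbcz, lz, excl, forces):
    """LJ(+Coulomb) over a half pair list; returns (epot, virial, min_r2)."""
    epot = 0.0
    vir = np.zeros((3, 3))
    rc2 = rc * rc
    minr2 = 1e30
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        if excl[k]:
            continue
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx > 0.5 * lx:
            dx -= lx
        elif dx < -0.5 * lx:
            dx += lx
        if dy > 0.5 * ly:
            dy -= ly
        elif dy < -0.5 * ly:
            dy += ly
        if pbcz:
            if dz > 0.5 * lz:
                dz -= lz
            elif dz < -0.5 * lz:
                dz += lz
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        if r2 < minr2:
            minr2 = r2
        ti = tidx[i]
        tj = tidx[j]
        s2 = sigsq[ti, tj] / r2
        s6 = s2 * s2 * s2
        e4 = eps4[ti, tj]
        # U = 4 eps (s^12 - s^6) - shift ; dU/dr * (1/r) = -24 eps (2 s^12 - s^6)/r^2
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
    return epot, vir, minr2


@njit(cache=True, fastmath=True)
def _bond_forces(pos, bi, bj, bk, br0, lx, ly, pbcz, lz, forces):
    epot = 0.0
    vir = np.zeros((3, 3))
    for n in range(bi.shape[0]):
        i = bi[n]
        j = bj[n]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= lx * np.rint(dx / lx)
        dy -= ly * np.rint(dy / ly)
        if pbcz:
            dz -= lz * np.rint(dz / lz)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - br0[n]
        epot += 0.5 * bk[n] * dr * dr
        fr = -bk[n] * dr / r
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


@njit(cache=True, fastmath=True)
def _angle_forces(pos, ai, aj, ak, akk, ath0, lx, ly, pbcz, lz, forces):
    """Harmonic angles i-j-k (j central); group virial about the central atom."""
    epot = 0.0
    vir = np.zeros((3, 3))
    for n in range(ai.shape[0]):
        i = ai[n]
        j = aj[n]
        k = ak[n]
        rij = np.empty(3)
        rkj = np.empty(3)
        for d in range(3):
            rij[d] = pos[i, d] - pos[j, d]
            rkj[d] = pos[k, d] - pos[j, d]
        for vec in (rij, rkj):
            vec[0] -= lx * np.rint(vec[0] / lx)
            vec[1] -= ly * np.rint(vec[1] / ly)
            if pbcz:
                vec[2] -= lz * np.rint(vec[2] / lz)
        r1 = np.sqrt(rij[0] ** 2 + rij[1] ** 2 + rij[2] ** 2)
        r2 = np.sqrt(rkj[0] ** 2 + rkj[1] ** 2 + rkj[2] ** 2)
        cost = (rij[0] * rkj[0] + rij[1] * rkj[1] + rij[2] * rkj[2]) / (r1 * r2)
        if cost > 1.0:
            cost = 1.0
        if cost < -1.0:
            cost = -1.0
        theta = np.arccos(cost)
        dth = theta - ath0[n]
        epot += 0.5 * akk[n] * dth * dth
        sint = np.sqrt(1.0 - cost * cost)
        if sint < 1e-8:
            sint = 1e-8
        coef = -akk[n] * dth / sint  # dU/d(cos theta)
        fi = np.empty(3)
        fk = np.empty(3)
        for d in range(3):
            fi[d] = -coef * (rkj[d] / (r1 * r2) - cost * rij[d] / (r1 * r1))
            fk[d] = -coef * (rij[d] / (r1 * r2) - cost * rkj[d] / (r2 * r2))
        for d in range(3):
            forces[i, d] += fi[d]
            forces[k, d] += fk[d]
            forces[j, d] -= fi[d] + fk[d]
        for a in range(3):
            for b in range(3):
                vir[a, b] += rij[a] * fi[b] + rkj[a] * fk[b]
    return epot, vir


# ---------------------------------------------------------------------------
# compiled force field


class _CompiledFF:
    """Force field flattened to arrays for the kernels, bound to one slab."""

    def __init__(self, slab: CrystalSlab, ff: ForceField):
        ff.validate_for_box(slab.box)
        species = sorted(set(slab.species.tolist()))
        smap = {s: i for i, s in enumerate(species)}
        nt = len(species)
        self.tidx = np.array([smap[s] for s in slab.species], dtype=np.int64)
        self.eps4 = np.zeros((nt, nt))
        self.sigsq = np.ones((nt, nt))
        self.ushift = np.zeros((nt, nt))
        rc = ff.cutoff
        for a in range(nt):
            for b in range(nt):
                eps, sig = ff.pair_params(species[a], species[b])
                self.eps4[a, b] = 4.0 * eps
                self.sigsq[a, b] = sig * sig
                s6 = (sig / rc) ** 6
                self.ushift[a, b] = 4.0 * eps * (s6 * s6 - s6)
        self.cutoff = rc
        self.qfac = COULOMB_CONSTANT / ff.permittivity if ff.coulomb else 0.0
        self.charges = slab.charges.astype(float)

        if slab.bonds is not None and len(slab.bonds):
            bi = slab.bonds[:, 0].astype(np.int64)
            bj = slab.bonds[:, 1].astype(np.int64)
            kk = np.empty(len(bi))
            r0 = np.empty(len(bi))
            for n, (i, j) in enumerate(zip(bi, bj)):
                key = (slab.species[i], slab.species[j])
                if key in ff.bonds:
                    kk[n], r0[n] = ff.bonds[key]
                elif key[::-1] in ff.bonds:
                    kk[n], r0[n] = ff.bonds[key[::-1]]
                else:
                    raise ValueError(f"no bond term for species pair {key}")
            self.bond_i, self.bond_j = bi, bj
            self.bond_k, self.bond_r0 = kk, r0
            self.bonded_pairs = set(zip(bi.tolist(), bj.tolist())) | set(
                zip(bj.tolist(), bi.tolist())
            )
        else:
            self.bond_i = np.empty(0, np.int64)
            self.bond_j = np.empty(0, np.int64)
            self.bond_k = np.empty(0)
            self.bond_r0 = np.empty(0)
            self.bonded_pairs = set()

        if slab.angles is not None and len(slab.angles):
            ai = slab.angles[:, 0].astype(np.int64)
            aj = slab.angles[:, 1].astype(np.int64)
            ak = slab.angles[:, 2].astype(np.int64)
            kk = np.empty(len(ai))
            t0 = np.empty(len(ai))
            for n in range(len(ai)):
                key = (slab.species[ai[n]], slab.species[aj[n]], slab.species[ak[n]])
                if key in ff.angles:
                    kk[n], t0[n] = ff.angles[key]
                elif key[::-1] in ff.angles:
                    kk[n], t0[n] = ff.angles[key[::-1]]
                else:
                    raise ValueError(f"no angle term for species triple {key}")
            self.ang_i, self.ang_j, self.ang_k = ai, aj, ak
            self.ang_kk, self.ang_t0 = kk, t0
        else:
            self.ang_i = np.empty(0, np.int64)
            self.ang_j = np.empty(0, np.int64)
            self.ang_k = np.empty(0, np.int64)
            self.ang_kk = np.empty(0)
            self.ang_t0 = np.empty(0)


_SKIN = 0.2  # nm Verlet skin


class _NeighborList:
    def __init__(self, slab: CrystalSlab, cutoff: float):
        self.rlist = cutoff + _SKIN
        self.box = slab.box
        self.pi = self.pj = None
        self.excl = None
        self.ref = None

    def update(self, pos: np.ndarray, bonded_pairs: set, force: bool = False) -> None:
        if not force and self.ref is not None:
            disp = np.abs(pos - self.ref).max()
            if disp < 0.5 * _SKIN:
                return
        lx, ly, lz = self.box.lengths
        pi, pj = _build_pairs(pos, lx, ly, self.box.pbc[2], lz, self.rlist)
        if len(pi) == 0 and len(pos) > 1:
            # capacity overflow fallback: brute force
            pi, pj = _build_pairs(pos, lx, ly, self.box.pbc[2], max(lz, 1.0), 1e9)
        self.pi, self.pj = pi, pj
        if bonded_pairs:
            self.excl = np.fromiter(
                ((int(a), int(b)) in bonded_pairs for a, b in zip(pi, pj)),
                dtype=bool, count=len(pi),
            )
        else:
            self.excl = np.zeros(len(pi), dtype=bool)
        self.ref = pos.copy()


def _eval_forces(slab, cff, nlist, indenter=None):
    pos = slab.positions
    lx, ly, lz = slab.box.lengths
    pbcz = slab.box.pbc[2]
    nlist.update(pos, cff.bonded_pairs)
    forces = np.zeros_like(pos)
    epot, vir, minr2 = _pair_forces(
        pos, nlist.pi, nlist.pj, cff.tidx, cff.eps4, cff.sigsq, cff.ushift,
        cff.charges, cff.qfac, cff.cutoff, lx, ly, pbcz, lz, nlist.excl, forces,
    )
    if minr2 < _OVERLAP_LIMIT**2:
        raise RuntimeError(
            f"particle overlap: minimum pair distance {np.sqrt(minr2):.4f} nm "
            f"< {_OVERLAP_LIMIT} nm (force blow-up guard)"
        )
    if len(cff.bond_i):
        eb, vb = _bond_forces(pos, cff.bond_i, cff.bond_j, cff.bond_k,
                              cff.bond_r0, lx, ly, pbcz, lz, forces)
        epot += eb
        vir += vb
    if len(cff.ang_i):
        ea, va = _angle_forces(pos, cff.ang_i, cff.ang_j, cff.ang_k,
                               cff.ang_kk, cff.ang_t0, lx, ly, pbcz, lz, forces)
        epot += ea
        vir += va
    if indenter is not None:
        fi, _, ei = indenter.particle_forces(pos)
        forces += fi
        epot += ei
    return forces, epot, vir


def compute_forces(slab: CrystalSlab, ff: ForceField, indenter=None):
    """Per-particle forces (kJ/mol/nm) and potential energy (kJ/mol)."""
    cff = _CompiledFF(slab, ff)
    nlist = _NeighborList(slab, cff.cutoff)
    forces, epot, _ = _eval_forces(slab, cff, nlist, indenter)
    return forces, float(epot)


# ---------------------------------------------------------------------------
# integration


@dataclass
class EngineState:
    """Mutable integration state; temperature is over unfrozen DOF only."""

    slab: CrystalSlab
    time: float = 0.0
    step_count: int = 0
    potential_energy: float = 0.0
    kinetic_energy: float = 0.0
    temperature: float = 0.0
    thermostat: Thermostat = field(default_factory=Thermostat)
    seed: int = 0


class Integrator:
    """Velocity-Verlet / Langevin (BAOAB) integrator bound to one slab.

    Mutates ``slab`` in place.  Deterministic for a given seed.
    """

    def __init__(
        self,
        slab: CrystalSlab,
        ff: ForceField,
        dt: float = 0.002,
        thermostat: Optional[Thermostat] = None,
        seed: int = 0,
        indenter=None,
    ):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.slab = slab
        self.ff = ff
        self.dt = dt
        self.thermostat = thermostat or Thermostat()
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.indenter = indenter
        self.cff = _CompiledFF(slab, ff)
        self.nlist = _NeighborList(slab, self.cff.cutoff)
        self.free = ~slab.frozen_mask
        self.masses_free = slab.masses[self.free, None]
        self.n_free_dof = 3 * int(self.free.sum())
        self.forces, self.epot, self.virial = _eval_forces(
            slab, self.cff, self.nlist, indenter
        )
        self.time = 0.0
        self.step_count = 0
        gamma = self.thermostat.friction
        self._c1 = np.exp(-gamma * dt) if gamma > 0 else 1.0
        self._c2 = np.sqrt(max(0.0, 1.0 - self._c1**2))

    # -- thermodynamic observables -----------------------------------------
    @property
    def kinetic_energy(self) -> float:
        v = self.slab.velocities[self.free]
        return float(0.5 * np.sum(self.masses_free * v * v))

    @property
    def temperature(self) -> float:
        if self.n_free_dof == 0:
            return 0.0
        return 2.0 * self.kinetic_energy / (self.n_free_dof * KB)

    def seed_velocities(self, temperature: float) -> None:
        """Maxwell-Boltzmann draw on unfrozen particles."""
        n = int(self.free.sum())
        sig = np.sqrt(KB * temperature / self.slab.masses[self.free])[:, None]
        v = self.rng.normal(size=(n, 3)) * sig
        v -= v.mean(axis=0)  # no net drift
        self.slab.velocities[self.free] = v
        self.slab.velocities[~self.free] = 0.0

    def step(self, n_steps: int = 1) -> None:
        dt = self.dt
        slab = self.slab
        free = self.free
        m = self.masses_free
        kT = KB * self.thermostat.target_temperature
        use_bath = self.thermostat.friction > 0
        for _ in range(n_steps):
            v = slab.velocities[free]
            v += 0.5 * dt * self.forces[free] / m
            slab.positions[free] += 0.5 * dt * v
            if use_bath:
                v = self._c1 * v + self._c2 * np.sqrt(kT / m) * self.rng.normal(
                    size=v.shape
                )
            slab.positions[free] += 0.5 * dt * v
            slab.velocities[free] = v
            if self.indenter is not None:
                self.indenter.advance(dt)
            self.forces, self.epot, self.virial = _eval_forces(
                slab, self.cff, self.nlist, self.indenter
            )
            v = slab.velocities[free]
            v += 0.5 * dt * self.forces[free] / m
            slab.velocities[free] = v
            self.time += dt
            self.step_count += 1
            if not np.isfinite(self.forces).all():
                raise RuntimeError(
                    f"non-finite force at step {self.step_count}"
                )

    def state(self) -> EngineState:
        return EngineState(
            slab=self.slab,
            time=self.time,
            step_count=self.step_count,
            potential_energy=self.epot,
            kinetic_energy=self.kinetic_energy,
            temperature=self.temperature,
            thermostat=self.thermostat,
            seed=self.seed,
        )


def step(integrator: Integrator, n_steps: int = 1) -> EngineState:
    """Advance the integrator and return the resulting state snapshot."""
    integrator.step(n_steps)
    return integrator.state()


def _slab_volume(slab: CrystalSlab) -> float:
    """Occupied volume: full box when bulk-periodic, else footprint x thickness."""
    if slab.box.pbc[2]:
        return float(np.prod(slab.box.lengths))
    z = slab.positions[:, 2]
    span = float(z.max() - z.min())
    layers = layer_indices(slab)
    if len(layers) > 1:
        span *= len(layers) / (len(layers) - 1)  # add one interlayer spacing
    if span <= 0:
        raise ValueError("zero occupied volume")
    return slab.box.footprint_area * span


def virial_stress(slab: CrystalSlab, ff: ForceField) -> StressTensor:
    """Instantaneous virial stress, MPa, tension positive.

    sigma = -(1/V) [ sum_i m_i v_i v_i^T + sum_pairs r_ij f_ij^T + bonded ],
    so a thermalized ideal gas reports hydrostatic pressure n k_B T / V and a
    compressed crystal has negative trace.  Frozen particles carry no kinetic
    term.
    """
    cff = _CompiledFF(slab, ff)
    nlist = _NeighborList(slab, cff.cutoff)
    _, _, vir = _eval_forces(slab, cff, nlist)
    free = ~slab.frozen_mask
    v = slab.velocities[free]
    kin = (slab.masses[free, None, None] * v[:, :, None] * v[:, None, :]).sum(axis=0)
    vol = _slab_volume(slab)
    kin_stress = -kin / vol * KJ_MOL_NM3_TO_MPA
    vir_stress = -vir / vol * KJ_MOL_NM3_TO_MPA
    total = 0.5 * (kin_stress + vir_stress + (kin_stress + vir_stress).T)
    return StressTensor(total=total, kinetic=kin_stress, virial=vir_stress)


def run_nvt(
    slab: CrystalSlab,
    ff: ForceField,
    duration: float,
    dt: float = 0.002,
    thermostat: Optional[Thermostat] = None,
    seed: int = 0,
    log_stride: int = 10,
    traj_stride: int = 0,
    indenter=None,
    initialize_velocities: bool = True,
):
    """Constant-volume run with scalar logging and optional trajectory frames.

    Returns ``(state, trajectory, log)``: final :class:`EngineState`, a list
    of position snapshots (possibly empty), and a tidy DataFrame of scalars
    including the Voigt stress components.
    """
    if duration < dt:
        raise ValueError(f"duration {duration} must be >= dt {dt}")
    thermostat = thermostat or Thermostat()
    integ = Integrator(slab, ff, dt=dt, thermostat=thermostat, seed=seed,
                       indenter=indenter)
    if initialize_velocities and thermostat.friction > 0:
        integ.seed_velocities(thermostat.target_temperature)
    n_steps = int(round(duration / dt))
    rows = []
    traj = []

    vol = _slab_volume(slab)

    def log_now():
        free_m = integ.free
        v = slab.velocities[free_m]
        kin = (slab.masses[free_m, None, None] * v[:, :, None] * v[:, None, :]).sum(axis=0)
        tot = -(kin + integ.virial) / vol * KJ_MOL_NM3_TO_MPA
        tot = 0.5 * (tot + tot.T)
        sv = np.array([tot[0, 0], tot[1, 1], tot[2, 2],
                       tot[1, 2], tot[0, 2], tot[0, 1]])
        rows.append(
            (integ.step_count, integ.time, integ.temperature, integ.epot,
             integ.kinetic_energy, *sv)
        )

    for s in range(n_steps):
        integ.step()
        if log_stride and integ.step_count % log_stride == 0:
            log_now()
        if traj_stride and integ.step_count % traj_stride == 0:
            traj.append(slab.positions.copy())
    if not rows:
        log_now()
    log = pd.DataFrame(
        rows,
        columns=["step", "time_ps", "T_K", "E_pot", "E_kin",
                 "sigma_xx", "sigma_yy", "sigma_zz",
                 "sigma_yz", "sigma_xz", "sigma_xy"],
    )
    return integ.state(), traj, log


def minimize_slab(
    slab: CrystalSlab, ff: ForceField, ftol: float = 1.0, max_iter: int = 500
) -> CrystalSlab:
    """Local energy minimization (L-BFGS) of unfrozen particle positions.

    ``ftol`` is the target maximum force component in kJ/mol/nm.
    """
    from scipy.optimize import minimize

    work = slab.copy()
    cff = _CompiledFF(work, ff)
    nlist = _NeighborList(work, cff.cutoff)
    free = ~work.frozen_mask
    x0 = work.positions[free].ravel().copy()

    def fun(x):
        work.positions[free] = x.reshape(-1, 3)
        f, e, _ = _eval_forces(work, cff, nlist)
        return e, -f[free].ravel()

    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "gtol": ftol * 1e-2})
    work.positions[free] = res.x.reshape(-1, 3)
    work.velocities[:] = 0.0
    return work
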