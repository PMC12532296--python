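"""Displacement-controlled spherical nanoindentation.

The indenter is driven into the slab at a constant penetration rate, held
stationary so the contact can equilibrate, then retracted at a (typically
slower) unloading rate; the reaction force on the indenter versus penetration
depth is the primary observable, analyzed downstream with the Oliver-Pharr
method.  The default indenter is an analytic repulsive sphere (quadratic
wall), the standard stand-in for a rigid atomistic tip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .crystal_builder import CrystalSlab, ForceField, layer_indices
from .md_engine import Integrator, Thermostat, _build_pairs, _pair_forces, _SKIN

__all__ = [
    "Indenter",
    "IndentationProtocol",
    "ForceDisplacementCurve",
    "indenter_force",
    "run_indentation",
    "spacing_ratio",
    "block_average",
]


@dataclass
class Indenter:
    """Spherical indenter.

    ``analytic_sphere``: particles inside the sphere (r < R) feel a radially
    outward force K (R - r)^2, i.e. potential K (R - r)^3 / 3.
    ``rigid_atomistic``: purely repulsive (WCA-truncated) Lennard-Jones wall
    measured from the sphere surface, emulating a rigid nanoparticle tip of
    unspecified material.
    """

    radius: float  # nm
    center: np.ndarray  # (3,) nm
    stiffness: float = 2000.0  # K, kJ/mol/nm^3 (analytic model)
    model: str = "analytic_sphere"
    wall_epsilon: float = 1.0  # kJ/mol (atomistic model)
    wall_sigma: float = 0.25  # nm (atomistic model)
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))  # nm/ps

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("indenter radius must be positive")
        if self.stiffness <= 0:
            raise ValueError("indenter stiffness must be positive")
        if self.model not in ("analytic_sphere", "rigid_atomistic"):
            raise ValueError(f"unknown indenter model {self.model!r}")
        self.center = np.asarray(self.center, dtype=float).copy()
        self.velocity = np.asarray(self.velocity, dtype=float).copy()

    def particle_forces(self, positions: np.ndarray):
        """(per-particle forces, reaction force on the indenter, energy).

        The reaction force is exactly minus the sum of particle forces.
        """
        d = positions - self.center
        r = np.linalg.norm(d, axis=1)
        forces = np.zeros_like(positions)
        energy = 0.0
        if self.model == "analytic_sphere":
            inside = (r < self.radius) & (r > 1e-12)
            if inside.any():
                pen = self.radius - r[inside]
                mag = self.stiffness * pen**2
                forces[inside] = (d[inside] / r[inside, None]) * mag[:, None]
                energy = float(self.stiffness * np.sum(pen**3) / 3.0)
        else:
            s = r - self.radius  # distance outside the sphere surface
            rc = self.wall_sigma * 2 ** (1 / 6)
            close = (s < rc) & (r > 1e-12)
            if close.any():
                ss = np.maximum(s[close], 0.05 * self.wall_sigma)
                sr6 = (self.wall_sigma / ss) ** 6
                e = 4 * self.wall_epsilon * (sr6**2 - sr6) + self.wall_epsilon
                mag = 24 * self.wall_epsilon * (2 * sr6**2 - sr6) / ss
                forces[close] = (d[close] / r[close, None]) * mag[:, None]
                energy = float(e.sum())
        reaction = -forces.sum(axis=0)
        return forces, reaction, energy

    def advance(self, dt: float) -> None:
        self.center += self.velocity * dt


def indenter_force(indenter: Indenter, positions: np.ndarray):
    """Functional wrapper: (per-particle forces, reaction force triple)."""
    forces, reaction, _ = indenter.particle_forces(positions)
    return forces, reaction


@dataclass
class IndentationProtocol:
    """Schedule of a displacement-controlled indentation run.

    Rates are in internal units (nm/ps; 1 nm/ps = 1000 m/s).  The hold phase
    keeps the indenter stationary with the thermostat on so dislocations can
    settle before unloading.
    """

    penetration_rate: float = 0.0083  # nm/ps
    max_depth: float = 0.5  # nm
    hold_duration: float = 10.0  # ps
    unloading_rate: float = 0.0008  # nm/ps
    dt: float = 0.002  # ps
    thermostat: Thermostat = field(default_factory=Thermostat)
    equilibration: float = 2.0  # ps before loading starts
    standoff: float = 0.1  # nm initial tip-surface clearance
    snapshot_stride: int = 0  # extra snapshots every n steps (0 = off)
    seed: int = 0

    def validate(self, slab: CrystalSlab, indenter: Indenter) -> None:
        if self.penetration_rate <= 0 or self.unloading_rate <= 0:
            raise ValueError("rates must be positive")
        if self.max_depth >= indenter.radius:
            raise ValueError(
                f"max_depth {self.max_depth} must stay below the indenter "
                f"radius {indenter.radius} for contact mechanics to apply"
            )
        z = slab.positions[:, 2]
        free_thickness = z.max() - z[slab.frozen_mask].max() if slab.frozen_mask.any() else z.max() - z.min()
        if self.max_depth >= free_thickness:
            raise ValueError(
                f"max_depth {self.max_depth} exceeds the unfrozen crystal "
                f"thickness {free_thickness:.3f}"
            )


@dataclass
class ForceDisplacementCurve:
    """Force-displacement record with per-sample phase labels."""

    time: np.ndarray  # ps
    depth: np.ndarray  # nm
    force: np.ndarray  # kJ/mol/nm, indentation-axis reaction on the tip
    phase: np.ndarray  # str: load | hold | unload
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.depth) == len(self.force) == len(self.phase) == n):
            raise ValueError("curve arrays must have equal length")

    def branch(self, phase: str) -> "ForceDisplacementCurve":
        m = self.phase == phase
        return ForceDisplacementCurve(
            self.time[m], self.depth[m], self.force[m], self.phase[m],
            dict(self.metadata),
        )


def block_average(curve: ForceDisplacementCurve, block: int = 50) -> ForceDisplacementCurve:
    """Non-overlapping block means of a raw curve (noise reduction for fits).

    Blocks never straddle a phase boundary; a trailing partial block is kept.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    ts, ds, fs, ps = [], [], [], []
    for ph in ("load", "hold", "unload"):
        m = curve.phase == ph
        if not m.any():
            continue
        t, d, f = curve.time[m], curve.depth[m], curve.force[m]
        for s in range(0, len(t), block):
            sl = slice(s, s + block)
            ts.append(t[sl].mean())
            ds.append(d[sl].mean())
            fs.append(f[sl].mean())
            ps.append(ph)
    meta = dict(curve.metadata)
    meta["block_average"] = block
    return ForceDisplacementCurve(
        np.array(ts), np.array(ds), np.array(fs), np.array(ps, dtype=object),
        meta,
    )


@njit(cache=True, fastmath=True)
def _lj_forces_fast(pos, pi, pj, tidx, eps4, sigsq, rc2, hlx, hly, lx, ly, forces):
    """Specialized LJ force loop for the indentation hot path (no virial)."""
    minr2 = 1e30
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx > hlx:
            dx -= lx
        elif dx < -hlx:
            dx += lx
        if dy > hly:
            dy -= ly
        elif dy < -hly:
            dy += ly
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        if r2 < minr2:
            minr2 = r2
        ti = tidx[i]
        tj = tidx[j]
        s2 = sigsq[ti, tj] / r2
        s6 = s2 * s2 * s2
        fr = 6.0 * eps4[ti, tj] * (2.0 * s6 * s6 - s6) / r2
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return minr2


@njit(cache=True, fastmath=True)
def _indent_phase(pos, vel, free, sig_v, inv_m, tidx, eps4, sigsq, ushift,
                  rc, lx, ly, lz, dt, c1, c2, n_steps, center, vz,
                  radius, stiffness, seed, depth_out, force_out):
    """BAOAB loop with the analytic spherical tip; records tip depth/force.

    Returns 0 on success, 1 on particle overlap, 2 on non-finite force.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    rlist = rc + 0.2
    rc2 = rc * rc
    hlx = 0.5 * lx
    hly = 0.5 * ly
    pi, pj = _build_pairs(pos, lx, ly, False, lz, rlist)
    ref = pos.copy()
    forces = np.zeros((n, 3))
    _lj_forces_fast(pos, pi, pj, tidx, eps4, sigsq, rc2, hlx, hly, lx, ly, forces)
    # tip contribution
    for i in range(n):
        dx = pos[i, 0] - center[0]
        dy = pos[i, 1] - center[1]
        dz = pos[i, 2] - center[2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < radius and r > 1e-12:
            mag = stiffness * (radius - r) * (radius - r) / r
            forces[i, 0] += mag * dx
            forces[i, 1] += mag * dy
            forces[i, 2] += mag * dz
    for s in range(n_steps):
        for i in range(n):
            if not free[i]:
                continue
            for d in range(3):
                vel[i, d] += 0.5 * dt * forces[i, d] * inv_m[i]
                pos[i, d] += 0.5 * dt * vel[i, d]
            if c2 > 0.0:
                for d in range(3):
                    vel[i, d] = c1 * vel[i, d] + c2 * sig_v[i] * np.random.standard_normal()
            for d in range(3):
                pos[i, d] += 0.5 * dt * vel[i, d]
        center[2] += vz * dt
        # neighbor refresh on displacement criterion
        maxd = 0.0
        for i in range(n):
            for d in range(3):
                ad = abs(pos[i, d] - ref[i, d])
                if ad > maxd:
                    maxd = ad
        if maxd > 0.1:
            pi, pj = _build_pairs(pos, lx, ly, False, lz, rlist)
            ref = pos.copy()
        forces[:] = 0.0
        minr2 = _lj_forces_fast(pos, pi, pj, tidx, eps4, sigsq, rc2, hlx, hly,
                                lx, ly, forces)
        if minr2 < 0.0001:
            return 1
        reaction_z = 0.0
        for i in range(n):
            dx = pos[i, 0] - center[0]
            dy = pos[i, 1] - center[1]
            dz = pos[i, 2] - center[2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < radius and r > 1e-12:
                mag = stiffness * (radius - r) * (radius - r) / r
                fx = mag * dx
                fy = mag * dy
                fz = mag * dz
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i, 2] += fz
                reaction_z -= fz
        ok = True
        for i in range(n):
            if free[i]:
                for d in range(3):
                    vel[i, d] += 0.5 * dt * forces[i, d] * inv_m[i]
                    if not np.isfinite(forces[i, d]):
                        ok = False
        if not ok:
            return 2
        depth_out[s] = center[2]
        force_out[s] = reaction_z
    return 0


def contact_plane_z(slab: CrystalSlab) -> float:
    """Depth zero: mean z of the topmost crystallographic layer."""
    return float(slab.positions[layer_indices(slab)[-1], 2].mean())


def run_indentation(
    slab: CrystalSlab,
    ff: ForceField,
    indenter: Indenter,
    protocol: IndentationProtocol,
    lateral_center: Optional[np.ndarray] = None,
):
    """Execute equilibrate -> load -> hold -> unload on a slab (in place).

    Returns ``(curve, snapshots)``; snapshots is a dict with at least
    ``reference`` (start of loading), ``max_depth`` and ``unloaded`` position
    arrays.  Depth is measured from the initial contact plane (mean topmost-
    layer z) and clamped at zero while the tip is above it; the reaction
    force is the z component on the tip, positive pushing the tip up.
    """
    protocol.validate(slab, indenter)
    if not slab.box.pbc[0] or slab.box.pbc[2]:
        raise ValueError("indentation expects a laterally periodic open-z slab")
    dt = protocol.dt
    z0 = contact_plane_z(slab)
    if lateral_center is None:
        lateral_center = 0.5 * slab.box.lengths[:2]
    start_z = z0 + indenter.radius + protocol.standoff
    indenter.center = np.array([lateral_center[0], lateral_center[1], start_z])
    indenter.velocity = np.zeros(3)

    n_eq = int(round(protocol.equilibration / dt))
    travel_in = protocol.max_depth + protocol.standoff
    n_load = int(round(travel_in / protocol.penetration_rate / dt))
    n_hold = int(round(protocol.hold_duration / dt))
    n_unload = int(round(travel_in / protocol.unloading_rate / dt))
    n_tot = n_load + n_hold + n_unload

    time = np.empty(n_tot)
    depth = np.empty(n_tot)
    force = np.empty(n_tot)
    phase = np.empty(n_tot, dtype=object)
    snapshots: dict[str, np.ndarray] = {}
    extra = []

    schedule = [
        ("load", n_load, -protocol.penetration_rate),
        ("hold", n_hold, 0.0),
        ("unload", n_unload, protocol.unloading_rate),
    ]

    use_fast = (
        indenter.model == "analytic_sphere"
        and (slab.bonds is None or len(slab.bonds) == 0)
        and (slab.angles is None or len(slab.angles) == 0)
        and not ff.coulomb
        and protocol.snapshot_stride == 0
    )
    if use_fast:
        from .md_engine import _CompiledFF
        from .units import KB

        cff = _CompiledFF(slab, ff)
        free = ~slab.frozen_mask
        temp = protocol.thermostat.target_temperature
        gamma = protocol.thermostat.friction
        rng = np.random.default_rng(protocol.seed)
        if gamma > 0:
            v = rng.normal(size=(int(free.sum()), 3)) * np.sqrt(
                KB * temp / slab.masses[free]
            )[:, None]
            v -= v.mean(axis=0)
            slab.velocities[free] = v
        sig_v = np.sqrt(KB * temp / slab.masses)
        inv_m = 1.0 / slab.masses
        c1 = np.exp(-gamma * dt) if gamma > 0 else 1.0
        c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
        lx, ly, lz = slab.box.lengths

        def run_phase(n_steps, vz, d_out, f_out, sub):
            code = _indent_phase(
                slab.positions, slab.velocities, free, sig_v, inv_m,
                cff.tidx, cff.eps4, cff.sigsq, cff.ushift, cff.cutoff,
                lx, ly, lz, dt, c1, c2, n_steps, indenter.center, vz,
                indenter.radius, indenter.stiffness,
                (protocol.seed * 8 + sub) % 2**31, d_out, f_out,
            )
            if code == 1:
                raise RuntimeError("particle overlap during indentation")
            if code == 2:
                raise RuntimeError("non-finite force during indentation")

        run_phase(n_eq, 0.0, np.empty(n_eq), np.empty(n_eq), 0)
        snapshots["reference"] = slab.positions.copy()
        k = 0
        for sub, (ph, n_steps, vz) in enumerate(schedule, start=1):
            sl = slice(k, k + n_steps)
            run_phase(n_steps, vz, depth[sl], force[sl], sub)
            phase[sl] = ph
            k += n_steps
            if ph == "hold":
                snapshots["max_depth"] = slab.positions.copy()
        # depth array currently holds the tip-center z trace
        depth[:] = np.maximum(0.0, z0 + indenter.radius - depth)
        time[:] = (np.arange(n_tot) + 1) * dt + n_eq * dt
    else:
        integ = Integrator(slab, ff, dt=dt, thermostat=protocol.thermostat,
                           seed=protocol.seed, indenter=indenter)
        if protocol.thermostat.friction > 0:
            integ.seed_velocities(protocol.thermostat.target_temperature)
        integ.step(n_eq)
        snapshots["reference"] = slab.positions.copy()
        k = 0
        for ph, n_steps, vz in schedule:
            indenter.velocity = np.array([0.0, 0.0, vz])
            for _ in range(n_steps):
                integ.step()
                _, reaction, _ = indenter.particle_forces(slab.positions)
                time[k] = integ.time
                depth[k] = max(0.0, z0 + indenter.radius - indenter.center[2])
                force[k] = reaction[2]
                phase[k] = ph
                if protocol.snapshot_stride and k % protocol.snapshot_stride == 0:
                    extra.append((k, slab.positions.copy()))
                k += 1
            if ph == "hold" and "max_depth" not in snapshots:
                snapshots["max_depth"] = slab.positions.copy()
    if n_hold == 0 and "max_depth" not in snapshots:
        snapshots["max_depth"] = slab.positions.copy()
    snapshots["unloaded"] = slab.positions.copy()
    for idx, pos in extra:
        snapshots[f"step_{idx}"] = pos

    meta = {
        "radius_nm": indenter.radius,
        "stiffness": indenter.stiffness,
        "model": indenter.model,
        "penetration_rate_nm_ps": protocol.penetration_rate,
        "unloading_rate_nm_ps": protocol.unloading_rate,
        "max_depth_nm": protocol.max_depth,
        "hold_ps": protocol.hold_duration,
        "dt_ps": dt,
        "temperature_K": protocol.thermostat.target_temperature,
        "seed": protocol.seed,
        "box_nm": slab.box.lengths.tolist(),
        "contact_plane_z_nm": z0,
        "force_unit": "kJ/mol/nm",
    }
    curve = ForceDisplacementCurve(time, depth, force, phase, meta)
    return curve, snapshots


def spacing_ratio(box, indenter_or_radius, axis: Optional[int] = None) -> float:
    """Indenter spacing: lateral period of the box over the tip diameter.

    Smaller values mean a larger tip relative to its periodic images, i.e. a
    denser indent array.  With unequal lateral lengths an axis must be named.
    """
    radius = (
        indenter_or_radius.radius
        if isinstance(indenter_or_radius, Indenter)
        else float(indenter_or_radius)
    )
    lx, ly = float(box.lengths[0]), float(box.lengths[1])
    if axis is None:
        if not np.isclose(lx, ly):
            raise ValueError(
                "lateral box lengths differ; name the axis for the spacing ratio"
            )
        lateral = lx
    else:
        lateral = (lx, ly)[axis]
    return lateral / (2.0 * radius)
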