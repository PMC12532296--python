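import numpy as np
import pytest

from nanodent.crystal_builder import Box, CrystalSlab, ForceField, make_toy_crystal
from nanodent.md_engine import (
    Integrator,
    Thermostat,
    compute_forces,
    run_nvt,
    virial_stress,
)
from nanodent.units import KB


def two_particle_slab(r, species=("X", "X"), box_len=10.0):
    pos = np.array([[1.0, 1.0, 5.0], [1.0 + r, 1.0, 5.0]])
    return CrystalSlab(
        positions=pos,
        velocities=np.zeros((2, 3)),
        species=np.array(species),
        charges=np.zeros(2),
        masses=np.ones(2) * 10.0,
        box=Box(np.array([box_len, box_len, box_len]), pbc=(True, True, False)),
        frozen_mask=np.zeros(2, bool),
        reference_positions=pos.copy(),
    )


LJ = dict(eps=2.0, sigma=0.3)


def lj_ff(cutoff=1.5):
    return ForceField(pair={("X", "X"): (LJ["eps"], LJ["sigma"])}, cutoff=cutoff)


class TestPairForces:
    def test_lj_minimum_zero_force(self):
        r = 2 ** (1 / 6) * LJ["sigma"]
        f, _ = compute_forces(two_particle_slab(r), lj_ff())
        assert np.abs(f).max() < 1e-10

    def test_lj_at_sigma(self):
        """At r = sigma the raw LJ potential is 0 and the force 24 eps/sigma."""
        f, e = compute_forces(two_particle_slab(LJ["sigma"]), lj_ff())
        # energy includes the cutoff shift only
        shift = 4 * LJ["eps"] * ((LJ["sigma"] / 1.5) ** 12 - (LJ["sigma"] / 1.5) ** 6)
        assert np.isclose(e, -shift, atol=1e-12)
        expect = 24 * LJ["eps"] / LJ["sigma"]
        assert np.isclose(f[0, 0], -expect)  # repulsive: pushed apart
        assert np.isclose(f[1, 0], expect)

    def test_bond_at_equilibrium(self):
        slab = two_particle_slab(0.2, species=("A", "B"))
        slab.bonds = np.array([[0, 1]])
        ff = ForceField(
            pair={("A", "A"): (0.0, 0.3), ("B", "B"): (0.0, 0.3)},
            cutoff=1.0,
            bonds={("A", "B"): (1000.0, 0.2)},
        )
        f, e = compute_forces(slab, ff)
        assert np.abs(f).max() < 1e-10

    def test_overlap_guard(self):
        with pytest.raises(RuntimeError, match="overlap"):
            compute_forces(two_particle_slab(0.005), lj_ff())

    def test_newtons_third_law(self, lj_fcc_bulk):
        slab, ff = lj_fcc_bulk
        pert = slab.copy()
        rng = np.random.default_rng(5)
        pert.positions = pert.positions + rng.normal(0, 0.01, pert.positions.shape)
        f, _ = compute_forces(pert, ff)
        assert np.abs(f.sum(axis=0)).max() < 1e-8

    def test_force_energy_consistency(self):
        """Central differences of the energy reproduce analytic forces."""
        slab, ff = make_toy_crystal("lj_fcc", (4, 4, 4), seed=0)
        rng = np.random.default_rng(11)
        slab.positions += rng.normal(0, 0.01, slab.positions.shape)
        f, _ = compute_forces(slab, ff)
        h = 1e-6
        for idx, ax in [(0, 0), (37, 1), (200, 2)]:
            up = slab.copy()
            up.positions[idx, ax] += h
            dn = slab.copy()
            dn.positions[idx, ax] -= h
            _, eu = compute_forces(up, ff)
            _, ed = compute_forces(dn, ff)
            fd = -(eu - ed) / (2 * h)
            assert abs(fd - f[idx, ax]) < 1e-6 * max(1.0, abs(f[idx, ax]))


class TestIntegration:
    def test_uniform_acceleration(self):
        """A single particle under the tip's constant-force region follows
        x0 + v0 t + f t^2 / 2m."""
        # emulate constant force with a harmonic bond of enormous r0 ~ linear
        slab = two_particle_slab(0.2)
        slab.frozen_mask[1] = True
        ff = lj_ff()
        # no interactions within cutoff: move particles apart
        slab.positions[1] = [8.0, 8.0, 1.0]
        slab.reference_positions = slab.positions.copy()
        integ = Integrator(slab, ff, dt=0.001, thermostat=Thermostat(0.0, 0.0))
        v0 = np.array([0.05, 0.0, 0.02])
        slab.velocities[0] = v0
        x0 = slab.positions[0].copy()
        integ.step(100)
        assert np.allclose(slab.positions[0], x0 + v0 * 0.1, atol=1e-10)

    def test_fixed_point(self):
        slab, ff = make_toy_crystal("lj_fcc", (4, 4, 4), seed=0)
        x0 = slab.positions.copy()
        integ = Integrator(slab, ff, dt=0.002, thermostat=Thermostat(0.0, 0.0))
        integ.step(10)
        # 0 K lattice is a stationary point: zero force, zero velocity
        assert np.allclose(slab.positions, x0, atol=1e-9)

    def test_determinism(self):
        out = []
        for _ in range(2):
            slab, ff = make_toy_crystal("lj_fcc", (4, 4, 4), seed=0)
            integ = Integrator(slab, ff, dt=0.002,
                               thermostat=Thermostat(12.0, 1.0), seed=42)
            integ.seed_velocities(12.0)
            integ.step(50)
            out.append(slab.positions.copy())
        assert np.array_equal(out[0], out[1])

    def test_nve_energy_conservation(self):
        slab, ff = make_toy_crystal("lj_fcc", (4, 4, 4), seed=0)
        integ = Integrator(slab, ff, dt=0.002, thermostat=Thermostat(12.0, 0.0),
                           seed=1)
        integ.seed_velocities(12.0)
        e0 = integ.epot + integ.kinetic_energy
        integ.step(10000)
        e1 = integ.epot + integ.kinetic_energy
        assert abs(e1 - e0) / abs(e0) < 1e-4

    def test_frozen_particles_never_move(self, lj_fcc_slab):
        slab, ff = lj_fcc_slab
        frozen_pos = slab.positions[slab.frozen_mask].copy()
        integ = Integrator(slab, ff, dt=0.004, thermostat=Thermostat(20.0, 2.0),
                           seed=3)
        integ.seed_velocities(20.0)
        integ.step(200)
        assert np.array_equal(slab.positions[slab.frozen_mask], frozen_pos)

    def test_nvt_temperature_control(self):
        slab, ff = make_toy_crystal("lj_fcc", (4, 4, 4), seed=0)
        _, _, log = run_nvt(slab, ff, 10.0, dt=0.004,
                            thermostat=Thermostat(12.0, 2.0), seed=2,
                            log_stride=25)
        tail = log["T_K"].iloc[len(log) // 2:]
        assert abs(tail.mean() - 12.0) / 12.0 < 0.05

    def test_duration_shorter_than_dt(self, lj_fcc_bulk):
        slab, ff = lj_fcc_bulk
        with pytest.raises(ValueError, match="duration"):
            run_nvt(slab.copy(), ff, 0.0001, dt=0.002)

    def test_langevin_equipartition_free_particles(self):
        """Langevin bath drives kinetic energy to 3/2 kT per particle."""
        n = 64
        rng = np.random.default_rng(0)
        pos = rng.uniform(1, 9, (n, 3))
        slab = CrystalSlab(
            positions=pos, velocities=np.zeros((n, 3)),
            species=np.array(["X"] * n), charges=np.zeros(n),
            masses=np.full(n, 10.0),
            box=Box(np.array([10.0, 10.0, 10.0]), (True, True, False)),
            frozen_mask=np.zeros(n, bool), reference_positions=pos.copy(),
        )
        ff = ForceField(pair={("X", "X"): (0.0, 0.3)}, cutoff=1.0)
        integ = Integrator(slab, ff, dt=0.01, thermostat=Thermostat(50.0, 5.0),
                           seed=8)
        integ.step(500)
        kes = []
        for _ in range(200):
            integ.step(5)
            kes.append(integ.kinetic_energy)
        mean_ke = np.mean(kes)
        expect = 1.5 * n * KB * 50.0
        se = np.std(kes, ddof=1) / np.sqrt(len(kes) / 10)  # correlated samples
        assert abs(mean_ke - expect) < 3 * max(se, 0.02 * expect)


class TestVirialStress:
    def test_static_minimum_is_stress_free(self, lj_fcc_bulk):
        slab, ff = lj_fcc_bulk
        st = virial_stress(slab, ff)
        assert np.abs(st.total).max() < 1.0  # MPa

    def test_ideal_gas_pressure(self):
        n = 200
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 5, (n, 3))
        t = 100.0
        m = 20.0
        vel = rng.normal(0, np.sqrt(KB * t / m), (n, 3))
        slab = CrystalSlab(
            positions=pos, velocities=vel, species=np.array(["X"] * n),
            charges=np.zeros(n), masses=np.full(n, m),
            box=Box(np.array([5.0, 5.0, 5.0]), (True, True, True)),
            frozen_mask=np.zeros(n, bool), reference_positions=pos.copy(),
        )
        ff = ForceField(pair={("X", "X"): (0.0, 0.1)}, cutoff=0.5)
        st = virial_stress(slab, ff)
        kin_t = (m * (vel**2).sum() / (3 * n * KB))  # realized temperature
        expect = n * KB * kin_t / 125.0 * 1.66054  # MPa
        assert np.isclose(st.pressure, expect, rtol=1e-10)

    def test_compression_gives_negative_trace(self, lj_fcc_bulk):
        slab, ff = lj_fcc_bulk
        comp = slab.copy()
        s = (1 - 0.01) ** (1 / 3)  # -1% volume
        comp.positions = comp.positions * s
        comp.box.lengths = comp.box.lengths * s
        st = virial_stress(comp, ff)
        assert np.trace(st.total) < 0

    def test_tension_gives_positive_trace(self, lj_fcc_bulk):
        slab, ff = lj_fcc_bulk
        ten = slab.copy()
        s = 1.01
        ten.positions = ten.positions * s
        ten.box.lengths = ten.box.lengths * s
        st = virial_stress(ten, ff)
        assert np.trace(st.total) > 0

    def test_symmetry(self, lj_fcc_bulk):
        slab, ff = lj_fcc_bulk
        pert = slab.copy()
        rng = np.random.default_rng(9)
        pert.positions = pert.positions + rng.normal(0, 0.01, pert.positions.shape)
        st = virial_stress(pert, ff)
        assert np.allclose(st.total, st.total.T, atol=1e-12)
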