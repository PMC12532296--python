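import numpy as np
import pytest

from nanodent.crystal_builder import UnitCell, make_toy_crystal
from nanodent.elastic_tensor import (
    ElasticTensor,
    StrainSample,
    _PeriodicSystem,
    apply_strain,
    compliance_tensor,
    directional_modulus,
    estimate_stiffness,
    face_normal,
    isotropic_stiffness,
    measure_strain_samples,
    voigt_strain_matrix,
)
from nanodent.units import KJ_MOL_NM3_TO_GPA


class TestApplyStrain:
    def test_uniaxial_scales_one_axis(self, lj_fcc_bulk):
        slab, _ = lj_fcc_bulk
        out = apply_strain(slab, 1, 0.004)
        assert np.isclose(out.box.lengths[0], slab.box.lengths[0] * 1.004)
        assert np.isclose(out.box.lengths[1], slab.box.lengths[1])
        assert np.isclose(out.box.lengths[2], slab.box.lengths[2])
        assert np.allclose(out.positions[:, 0], slab.positions[:, 0] * 1.004)

    def test_zero_is_identity(self, lj_fcc_bulk):
        slab, _ = lj_fcc_bulk
        out = apply_strain(slab, 3, 0.0)
        assert np.allclose(out.positions, slab.positions)

    def test_shear_maps_symmetrically(self, lj_fcc_bulk):
        """Voigt xy shear gamma: x gains gamma/2 * y and vice versa; the
        volume change is O(gamma^2)."""
        slab, _ = lj_fcc_bulk
        g = 0.012
        out = apply_strain(slab, 6, g)
        expect = slab.positions.copy()
        expect[:, 0] += g / 2 * slab.positions[:, 1]
        expect[:, 1] += g / 2 * slab.positions[:, 0]
        assert np.allclose(out.positions, expect)
        h = out.metadata["box_matrix"]
        vol0 = float(np.prod(slab.box.lengths))
        assert abs(abs(np.linalg.det(h)) / vol0 - 1.0) < g**2

    def test_elastic_regime_guard(self, lj_fcc_bulk):
        slab, _ = lj_fcc_bulk
        with pytest.raises(ValueError, match="elastic-regime"):
            apply_strain(slab, 1, 0.05)

    def test_strain_matrix_components(self):
        m = voigt_strain_matrix(4, 0.01)
        assert m[1, 2] == m[2, 1] == 0.005
        assert np.count_nonzero(m) == 2


def _samples_from_tensor(c, magnitudes=(0.004, 0.008, 0.012), noise=0.0, rng=None):
    samples = []
    for j in range(1, 7):
        for mag in magnitudes:
            for sg in (1.0, -1.0):
                eps = np.zeros(6)
                eps[j - 1] = sg * mag
                sig = c @ eps
                if noise:
                    sig = sig + rng.normal(0, noise, 6)
                samples.append(StrainSample(j, sg * mag, sig, np.zeros(6)))
    return samples


class TestEstimateStiffness:
    def test_noiseless_recovery_is_exact(self):
        c = isotropic_stiffness(100.0, 50.0, 25.0).c
        est = estimate_stiffness(_samples_from_tensor(c))
        assert np.allclose(est.c, c, atol=1e-10)

    def test_noisy_recovery_within_three_se(self):
        """Monte-Carlo: each recovered entry lies within 3 standard errors of
        truth (estimated over 100 noisy replicates)."""
        c = isotropic_stiffness(100.0, 50.0, 25.0).c
        rng = np.random.default_rng(0)
        noise = 1.0  # GPa, ~1% of C11
        reps = np.array(
            [estimate_stiffness(_samples_from_tensor(c, noise=noise, rng=rng)).c
             for _ in range(100)]
        )
        mean = reps.mean(axis=0)
        se = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
        assert np.all(np.abs(mean - c) <= 3 * se + 1e-9)

    def test_missing_component_reported(self):
        c = isotropic_stiffness(100.0, 50.0).c
        samples = [s for s in _samples_from_tensor(c) if s.component != 4]
        with pytest.raises(ValueError, match=r"\[4\]"):
            estimate_stiffness(samples)

    def test_lj_fcc_matches_energy_density_oracle(self, lj_fcc_bulk):
        """Athermal stress-strain stiffness vs central differences of the
        lattice energy per reference volume (independent brute-force route)."""
        slab, ff = lj_fcc_bulk
        samples = measure_strain_samples(slab, ff, temperature=0.0)
        est = estimate_stiffness(samples)
        vol0 = float(np.prod(slab.box.lengths))

        def energy(strained):
            sys_ = _PeriodicSystem(strained, ff, strained.metadata.get("box_matrix"))
            return sys_.forces_energy_virial()[1]

        d = 0.004
        e0 = energy(slab)
        # C11 and C44 from pure second differences, C12 from a mixed one
        c11 = (energy(apply_strain(slab, 1, d)) - 2 * e0
               + energy(apply_strain(slab, 1, -d))) / (d * d) / vol0
        c44 = (energy(apply_strain(slab, 4, d)) - 2 * e0
               + energy(apply_strain(slab, 4, -d))) / (d * d) / vol0
        epp = energy(apply_strain(apply_strain(slab, 1, d), 2, d))
        epm = energy(apply_strain(apply_strain(slab, 1, d), 2, -d))
        emp = energy(apply_strain(apply_strain(slab, 1, -d), 2, d))
        emm = energy(apply_strain(apply_strain(slab, 1, -d), 2, -d))
        c12 = (epp - epm - emp + emm) / (4 * d * d) / vol0
        for fd, ss in ((c11, est.c[0, 0]), ((c12), est.c[0, 1]), (c44, est.c[3, 3])):
            fd_gpa = fd * KJ_MOL_NM3_TO_GPA
            assert abs(fd_gpa - ss) / abs(fd_gpa) < 0.05

    def test_cubic_symmetry_of_lj_fcc(self, lj_fcc_bulk):
        slab, ff = lj_fcc_bulk
        est = estimate_stiffness(measure_strain_samples(slab, ff, temperature=0.0))
        c = est.c
        assert np.isclose(c[0, 0], c[1, 1], rtol=1e-3)
        assert np.isclose(c[3, 3], c[4, 4], rtol=1e-3)
        assert np.isclose(c[0, 1], c[0, 2], rtol=1e-3)
        assert est.positive_definite

    def test_low_temperature_sampling_close_to_athermal(self, lj_fcc_bulk):
        """Finite-T NVT sampling at 2 K agrees with the static route ~10%."""
        slab, ff = lj_fcc_bulk
        cold = estimate_stiffness(
            measure_strain_samples(slab, ff, magnitudes=(0.008,),
                                   temperature=2.0, duration=1.6, seed=3)
        )
        static = estimate_stiffness(
            measure_strain_samples(slab, ff, magnitudes=(0.008,), temperature=0.0)
        )
        assert abs(cold.c[0, 0] - static.c[0, 0]) / static.c[0, 0] < 0.10


class TestDirectionalModulus:
    def test_isotropic_same_in_all_directions(self):
        t = isotropic_stiffness(100.0, 50.0)
        rng = np.random.default_rng(1)
        dirs = rng.normal(size=(100, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        vals = np.array([directional_modulus(t, n) for n in dirs])
        expect = 50.0 * 200.0 / 150.0  # (C11-C12)(C11+2C12)/(C11+C12)
        assert np.allclose(vals, expect, rtol=1e-10)
        assert vals.max() - vals.min() < 1e-8

    def test_cubic_100_closed_form(self):
        t = isotropic_stiffness(100.0, 50.0, 40.0)  # cubic, not isotropic
        e100 = directional_modulus(t, np.array([1.0, 0.0, 0.0]))
        expect = 50.0 * 200.0 / 150.0
        assert np.isclose(e100, expect, rtol=1e-10)

    def test_sign_symmetry(self):
        t = isotropic_stiffness(80.0, 30.0, 45.0)
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            assert np.isclose(
                directional_modulus(t, n), directional_modulus(t, -n), rtol=1e-12
            )

    def test_unnormalized_direction_rejected(self):
        t = isotropic_stiffness(100.0, 50.0)
        with pytest.raises(ValueError, match="unit"):
            directional_modulus(t, np.array([2.0, 0.0, 0.0]))

    def test_positive_for_spd(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 6))
        t = ElasticTensor(a @ a.T + 6 * np.eye(6))
        dirs = rng.normal(size=(20, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        assert min(directional_modulus(t, n) for n in dirs) > 0

    def test_voigt_round_trip(self):
        t = isotropic_stiffness(100.0, 50.0, 40.0)
        s4 = compliance_tensor(t)
        sv = np.empty((6, 6))
        idx = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]
        for a, (i, j) in enumerate(idx):
            for b, (k, l) in enumerate(idx):
                f = (2.0 if a >= 3 else 1.0) * (2.0 if b >= 3 else 1.0)
                sv[a, b] = s4[i, j, k, l] * f
        assert np.allclose(sv, t.s, atol=1e-12)


class TestFaceNormal:
    def test_cubic_001(self, simple_cubic_cell):
        assert np.allclose(face_normal(simple_cubic_cell, (0, 0, 1)), [0, 0, 1])

    def test_cubic_110(self, simple_cubic_cell):
        n = face_normal(simple_cubic_cell, (1, 1, 0))
        assert np.allclose(n, np.array([1, 1, 0]) / np.sqrt(2))

    def test_orthorhombic_011(self):
        cell = UnitCell(
            lattice_vectors=np.diag([1.0, 2.0, 3.0]),
            species=["X"], frac_coords=np.zeros((1, 3)),
            charges=np.zeros(1), masses=np.ones(1),
        )
        n = face_normal(cell, (0, 1, 1))
        expect = np.array([0.0, 1 / 2, 1 / 3])
        assert np.allclose(n, expect / np.linalg.norm(expect))

    def test_antiparallel_faces_same_modulus(self, simple_cubic_cell):
        t = isotropic_stiffness(100.0, 50.0, 40.0)
        n1 = face_normal(simple_cubic_cell, (1, 2, 3))
        n2 = face_normal(simple_cubic_cell, (-1, -2, -3))
        assert np.allclose(n1, -n2)
        assert np.isclose(
            directional_modulus(t, n1), directional_modulus(t, n2), rtol=1e-12
        )

    def test_zero_hkl_rejected(self, simple_cubic_cell):
        with pytest.raises(ValueError):
            face_normal(simple_cubic_cell, (0, 0, 0))
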