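import numpy as np
import pytest

from actomyo import mechanics as mech
from actomyo.params import Domain, ParameterSet, drag_coefficient


def numerical_gradient(energy_fn, points, eps=1e-6):
    """Central finite differences of an energy over a stack of points."""
    points = np.asarray(points, dtype=float)
    grad = np.zeros_like(points)
    for i in range(points.shape[0]):
        for k in range(3):
            pp = points.copy()
            pp[i, k] += eps
            pm = points.copy()
            pm[i, k] -= eps
            grad[i, k] = (energy_fn(pp) - energy_fn(pm)) / (2 * eps)
    return grad


class TestExtensional:
    def test_equilibrium_zero(self):
        f0, f1 = mech.extensional_forces([0, 0, 0], [140, 0, 0], 140.0, 2.0)
        assert np.allclose(f0, 0) and np.allclose(f1, 0)

    def test_hooke_pair(self):
        f0, f1 = mech.extensional_forces([0, 0, 0], [141, 0, 0], 140.0, 2.0)
        assert np.allclose(f0, [2, 0, 0])    # contractile: pulled together
        assert np.allclose(f1, [-2, 0, 0])
        assert np.allclose(f0 + f1, 0)

    def test_matches_numerical_gradient(self, rng):
        for _ in range(10):
            pts = rng.uniform(0, 100, size=(2, 3))
            f0, f1 = mech.extensional_forces(pts[0], pts[1], 70.0, 1.3)
            grad = numerical_gradient(
                lambda p: mech.extensional_energy(p[0], p[1], 70.0, 1.3), pts)
            f = np.array([f0, f1])
            assert np.allclose(f, -grad, rtol=1e-6, atol=1e-8)


class TestBending:
    def test_collinear_zero(self):
        fs = mech.bending_forces([0, 0, 0], [1, 0, 0], [2, 0, 0], 0.0, 264.0)
        assert all(np.allclose(f, 0) for f in fs)

    def test_right_angle_matches_numerical_gradient(self):
        pts = np.array([[0.0, 0, 0], [100.0, 0, 0], [100.0, 100.0, 0]])
        fa, fb, fc = mech.bending_forces(*pts, 0.0, 264.0)
        grad = numerical_gradient(
            lambda p: mech.bending_energy(p[0], p[1], p[2], 0.0, 264.0), pts)
        assert np.allclose([fa, fb, fc], -grad, rtol=1e-6, atol=1e-8)
        # restoring torque magnitude kb * pi/2 about the vertex
        torque = np.cross(pts[0] - pts[1], fa) + np.cross(pts[2] - pts[1], fc)
        assert np.linalg.norm(torque) == pytest.approx(0.0, abs=1e-9)

    def test_random_triplets_gradient_and_net_force(self, rng):
        for _ in range(10):
            pts = rng.uniform(0, 50, size=(3, 3))
            fa, fb, fc = mech.bending_forces(*pts, 0.1, 37.0)
            assert np.allclose(fa + fb + fc, 0, atol=1e-12)
            grad = numerical_gradient(
                lambda p: mech.bending_energy(p[0], p[1], p[2], 0.1, 37.0), pts)
            assert np.allclose([fa, fb, fc], -grad, rtol=1e-5, atol=1e-7)


class TestRepulsion:
    def test_zero_at_contact_threshold(self):
        s1 = [[0, 0, 0], [100, 0, 0]]
        s2 = [[0, 0, 7], [100, 0, 7]]
        *forces, r12 = mech.repulsive_forces(s1, s2, 1.63, 7.0)
        assert r12 == pytest.approx(7.0)
        assert all(np.allclose(f, 0) for f in forces)

    def test_half_overlap_magnitude(self):
        s1 = [[0, 0, 0], [100, 0, 0]]
        s2 = [[0, 0, 3.5], [100, 0, 3.5]]
        f_p1, f_p2, f_q1, f_q2, r12 = mech.repulsive_forces(s1, s2, 1.63, 7.0)
        total_on_2 = f_q1 + f_q2
        assert np.linalg.norm(total_on_2) == pytest.approx(1.63 * 3.5)
        assert total_on_2[2] > 0          # pushed away from segment 1
        assert np.allclose(f_p1 + f_p2, -total_on_2)

    def test_matches_numerical_gradient_in_overlap(self):
        s1 = np.array([[0.0, 0, 0], [60.0, 0, 0]])
        s2 = np.array([[10.0, 4.0, 3.0], [70.0, 6.0, 4.0]])
        f_p1, f_p2, f_q1, f_q2, r12 = mech.repulsive_forces(s1, s2, 1.63, 7.0)
        assert 0 < r12 < 7.0
        pts = np.vstack([s1, s2])
        grad = numerical_gradient(
            lambda p: mech.repulsive_energy(p[:2], p[2:], 1.63, 7.0), pts)
        assert np.allclose([f_p1, f_p2, f_q1, f_q2], -grad, rtol=1e-4, atol=1e-7)

    def test_relaxation_decreases_energy(self):
        # pure repulsive relaxation of two overlapping parallel segments
        s1 = np.array([[0.0, 0, 0], [60.0, 0, 0]])
        s2 = np.array([[0.0, 0, 2.0], [60.0, 0, 2.0]])
        energy = [mech.repulsive_energy(s1, s2, 1.63, 7.0)]
        for _ in range(50):
            f_p1, f_p2, f_q1, f_q2, _ = mech.repulsive_forces(s1, s2, 1.63, 7.0)
            s1 = s1 + 0.05 * np.array([f_p1, f_p2])
            s2 = s2 + 0.05 * np.array([f_q1, f_q2])
            energy.append(mech.repulsive_energy(s1, s2, 1.63, 7.0))
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(energy, energy[1:]))
        assert energy[-1] < energy[0]


class TestWalls:
    def test_interior_zero(self, domain):
        assert np.allclose(mech.wall_forces([100, 100, 100], domain, 1.0), 0)

    def test_beyond_x_wall(self, domain):
        f = mech.wall_forces([domain.size_x + 10, 0, 100], domain, 1.0)
        assert np.allclose(f, [-10, 0, 0])

    def test_beyond_y_extent_free(self, domain):
        # y is periodic: no wall force regardless of the y coordinate
        f = mech.wall_forces([100, 2 * domain.size_y, 100], domain, 1.0)
        assert np.allclose(f, 0)


class TestLeverRule:
    @pytest.mark.parametrize("s,expected_pointed,expected_barbed", [
        (0.0, [4, 0, 0], [0, 0, 0]),
        (0.5, [2, 0, 0], [2, 0, 0]),
        (0.25, [3, 0, 0], [1, 0, 0]),
    ])
    def test_examples(self, s, expected_pointed, expected_barbed):
        fp, fb = mech.redistribute_arm_force(s, [4.0, 0, 0])
        assert np.allclose(fp, expected_pointed)
        assert np.allclose(fb, expected_barbed)

    def test_rejects_bad_fraction(self):
        with pytest.raises(ValueError):
            mech.redistribute_arm_force(1.5, [1, 0, 0])


class TestDrag:
    def test_sphere_limit(self):
        mu = 5e-7
        assert drag_coefficient(7.0, 7.0, mu) == pytest.approx(3 * np.pi * mu * 7.0)

    def test_monotone_in_length(self):
        assert drag_coefficient(280, 7, 5e-7) > drag_coefficient(140, 7, 5e-7)

    def test_hand_evaluation(self):
        # zeta = 3 pi mu rc (3 + 2 r0/rc)/5 at r0=140, rc=7
        mu = 5e-7
        expected = 3 * np.pi * mu * 7.0 * (3 + 2 * 140 / 7) / 5
        assert drag_coefficient(140, 7, mu) == pytest.approx(expected)
        assert expected == pytest.approx(2.8369e-4, rel=1e-3)


class TestSystemConsistency:
    """The compiled kernel and the NumPy reference are the same force field."""

    def test_kernel_matches_reference_single_step(self):
        from actomyo._kernels import run_kernel
        from actomyo.fixtures import make_fixture
        from actomyo.flatten import (build_system, compute_forces,
                                     rebuild_repulsion_pairs)

        st = make_fixture("contractile_unit")
        st.filaments[0].points += np.random.default_rng(1).normal(
            scale=5, size=st.filaments[0].points.shape)
        sys_ = build_system(st)
        rebuild_repulsion_pairs(sys_, st.domain, st.params)
        F = compute_forces(sys_, st.params, st.domain)
        assert np.allclose(F.sum(axis=0), 0, atol=1e-10)  # internal forces
        expected = sys_.P + F * st.params.dt / sys_.zeta[:, None]
        expected[:, 1] %= st.domain.size_y
        run_kernel(sys_.P, sys_.zeta, sys_.noise_amp, np.zeros((1, 1, 3)), 1,
                   st.params.dt,
                   st.domain.size_y, sys_.springs_i, sys_.springs_f,
                   sys_.axial_i, sys_.axial_f, sys_.angles_i, sys_.angles_f,
                   sys_.rep_pairs, st.params.kr_repulsion, st.params.rc_actin,
                   st.params.k_wall, st.domain.size_x, st.domain.size_z,
                   False)
        assert np.allclose(sys_.P, expected, rtol=0, atol=1e-10)

    def test_noiseless_relaxation_decreases_total_energy(self):
        from actomyo._kernels import run_kernel
        from actomyo.fixtures import make_fixture
        from actomyo.flatten import (build_system, rebuild_repulsion_pairs,
                                     total_energy)

        st = make_fixture("acp_bridge")
        rng = np.random.default_rng(7)
        for f in st.filaments:
            f.points += rng.normal(scale=8.0, size=f.points.shape)
        sys_ = build_system(st)
        rebuild_repulsion_pairs(sys_, st.domain, st.params)
        energies = [total_energy(sys_, st.params, st.domain)]
        for _ in range(20):
            run_kernel(sys_.P, sys_.zeta, sys_.noise_amp, np.zeros((1, 1, 3)),
                       50, st.params.dt,
                       st.domain.size_y, sys_.springs_i, sys_.springs_f,
                       sys_.axial_i, sys_.axial_f, sys_.angles_i, sys_.angles_f,
                       sys_.rep_pairs, st.params.kr_repulsion,
                       st.params.rc_actin, st.params.k_wall, st.domain.size_x,
                       st.domain.size_z, False)
            energies.append(total_energy(sys_, st.params, st.domain))
        assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(energies, energies[1:]))
        assert energies[-1] < energies[0]
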