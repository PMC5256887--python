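import numpy as np
import pytest

from actomyo.observables import (adjacent_tangent_cosines, antiparallel_fraction_y,
                                 buckling_census, bundle_tension,
                                 compaction_metrics, microscopic_forces,
                                 orientation_stats, persistence_length,
                                 shape_ratios, sigma_x, sustainability)
from actomyo.params import Domain, ParameterSet
from actomyo.state import CrossLinker, MotorEnsemble


def spanning_filament_state(make_state, strain=None, n_bonds=14):
    """One filament whose contour exactly closes the periodic y length."""
    p = ParameterSet()
    domain = Domain(size_x=1000, size_y=2000, size_z=500)
    bond = domain.size_y / n_bonds
    strain = bond - p.r0_actin if strain is None else strain
    ys = (3.0 + np.arange(n_bonds + 1) * (p.r0_actin + strain)) % domain.size_y
    pts = np.column_stack([np.full(n_bonds + 1, 500.0), ys,
                           np.full(n_bonds + 1, 250.0)])
    st = make_state([pts], params=p, domain=domain)
    return st, strain


class TestBundleTension:
    def test_relaxed_network_zero(self, make_state):
        pts = [[100, 100, 100], [100, 240, 100], [100, 380, 100]]
        st = make_state([pts])
        assert bundle_tension(st) == pytest.approx(0.0, abs=1e-9)

    def test_spanning_filament_uniform_strain(self, make_state):
        st, strain = spanning_filament_state(make_state)
        expected = st.params.ks_actin * strain   # kappa_s * delta per section
        assert strain > 0
        assert bundle_tension(st) == pytest.approx(expected, rel=1e-9)

    def test_compressed_filament_negative(self, make_state):
        st, _ = spanning_filament_state(make_state, n_bonds=15)
        strain = 2000 / 15 - st.params.r0_actin
        assert strain < 0
        assert bundle_tension(st) == pytest.approx(st.params.ks_actin * strain,
                                                   rel=1e-9)

    def test_empty_state_zero(self, make_state):
        st = make_state([])
        assert bundle_tension(st) == 0.0


class TestSustainability:
    def test_constant_tension_fully_sustained(self):
        t = np.linspace(0, 10, 50)
        assert sustainability(t, np.full(50, 3.0)) == pytest.approx(1.0)

    def test_decayed_tension_near_zero(self):
        t = np.linspace(0, 100, 400)
        tension = np.where(t < 5, 10.0, 1e-4)
        assert sustainability(t, tension) < 0.01

    def test_ramp_to_peak_at_end_clips_to_one(self):
        t = np.linspace(0, 10, 50)
        assert sustainability(t, t.copy()) == pytest.approx(0.875, rel=0.02)

    def test_nonpositive_peak_flagged(self):
        t = np.linspace(0, 10, 20)
        assert sustainability(t, np.full(20, -1.0)) is None


class TestMicroscopicForces:
    def test_acp_force_aligned_with_barbed_direction(self, make_state):
        p = ParameterSet()
        pts = [[500, 1000, 250], [500, 1140, 250], [500, 1280, 250]]
        st = make_state([pts], params=p)
        fil = st.filaments[0]
        acp = CrossLinker(fil.site_position(0, 0, p) - [0, p.r0_acp + 8.0, 0])
        st.acps.append(acp)
        st.bind_site((fil, 0, 0), "acp", acp, 0)
        f_acp, _ = microscopic_forces(st)
        # stretched by 8 nm, arm axis = +y = barbed direction
        assert f_acp[0] == pytest.approx(p.ks_acp * 8.0)

    def test_acp_force_perpendicular_is_zero(self, make_state):
        p = ParameterSet()
        pts = [[500, 1000, 250], [500, 1140, 250]]
        st = make_state([pts], params=p)
        fil = st.filaments[0]
        acp = CrossLinker(fil.site_position(0, 0, p) - [p.r0_acp + 8.0, 0, 0])
        st.acps.append(acp)
        st.bind_site((fil, 0, 0), "acp", acp, 0)
        f_acp, _ = microscopic_forces(st)
        assert f_acp[0] == pytest.approx(0.0, abs=1e-9)

    def test_motor_force_divided_by_heads(self, make_state):
        p = ParameterSet()
        pts = [[500, 1000, 250], [500, 1140, 250]]
        st = make_state([pts], params=p)
        fil = st.filaments[0]
        x_par = 8.0 / p.ks_motor_long   # total longitudinal force 8 pN
        anchor_y = fil.site_position(0, 10, p)[1] - x_par
        backbone = np.array([[513.5, anchor_y + i * p.r0_motor_backbone, 250]
                             for i in range(4)])
        motor = MotorEnsemble(backbone, n_arms=p.n_arms)
        st.motors.append(motor)
        st.bind_site((fil, 0, 10), "motor", motor, 0)
        _, f_m = microscopic_forces(st)
        assert f_m[0] == pytest.approx(8.0 / p.n_heads)


class TestSigmaX:
    def test_collapsed_zero(self, make_state):
        st = make_state([[[200, 0, 0], [200, 140, 0]]])
        assert sigma_x(st) == 0.0

    def test_symmetric_two_values(self, make_state):
        st = make_state([[[100, 0, 0], [100, 140, 0]],
                         [[300, 0, 0], [300, 140, 0]]])
        assert sigma_x(st) == pytest.approx(100.0)

    def test_uniform_moment(self, make_state, rng):
        xs = rng.uniform(0, 600, size=2000)
        pts = np.column_stack([xs, np.linspace(0, 1000, 2000),
                               np.full(2000, 5.0)])
        st = make_state([pts])
        assert sigma_x(st) == pytest.approx(600 / np.sqrt(12), rel=0.05)

    def test_requires_two_points(self, make_state):
        st = make_state([])
        with pytest.raises(ValueError):
            sigma_x(st)

    def test_translation_and_reflection_invariance(self, make_state, rng):
        pts = rng.uniform(0, 500, size=(40, 3))
        st1 = make_state([pts])
        shifted = pts + np.array([0.0, 123.0, 0.0])
        st2 = make_state([shifted])
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        st3 = make_state([mirrored])
        assert sigma_x(st2) == pytest.approx(sigma_x(st1))
        assert sigma_x(st3) == pytest.approx(sigma_x(st1))


class TestCompaction:
    def test_exponential_series_oracle(self):
        # sigma(t) = 100 exp(-t/2) + 50; the rate falls to 1% of its 5-s
        # baseline at t = 2 ln(50 / 0.1836) ~ 11.2 s (numerical oracle)
        t = np.arange(0, 15.0, 0.05)
        sigma = 100 * np.exp(-t / 2) + 50
        res = compaction_metrics(t, sigma)
        assert res.reached
        assert res.compaction_time == pytest.approx(11.2, abs=0.6)
        assert res.sigma_xc == pytest.approx(
            100 * np.exp(-res.compaction_time / 2) + 50, rel=0.01)

    def test_constant_series_not_reached(self):
        t = np.arange(0, 10.0, 0.1)
        res = compaction_metrics(t, np.full_like(t, 80.0))
        assert not res.reached
        assert res.compaction_time is None

    def test_v_shaped_series_first_crossing(self):
        t = np.arange(0, 20.0, 0.05)
        sigma = np.where(t < 8, 200 - 15 * t, 80 + 10 * (t - 8))
        res = compaction_metrics(t, sigma)
        assert res.reached
        assert 7.0 < res.compaction_time < 9.5

    def test_requires_baseline_coverage(self):
        with pytest.raises(ValueError):
            compaction_metrics([0, 1, 2], [3, 2, 1])


class TestBuckling:
    def test_straight_filament_ratio_one(self, make_state):
        st = make_state([[[0, 0, 0], [0, 140, 0], [0, 280, 0]]])
        ratios = shape_ratios(st)
        assert list(ratios.values()) == [pytest.approx(1.0)]

    def test_semicircle_not_buckled(self, make_state):
        # semicircular arc: end-to-end / contour = 2/pi ~ 0.637 > 0.6
        th = np.linspace(0, np.pi, 41)
        r = 500.0
        pts = np.column_stack([r * np.cos(th), r * np.sin(th) + 1000,
                               np.full_like(th, 250)]) + [600, 0, 0]
        st = make_state([pts])
        ratio = list(shape_ratios(st).values())[0]
        assert ratio == pytest.approx(2 / np.pi, rel=0.01)
        _, n, _ = buckling_census([shape_ratios(st)])
        assert n == 0

    def test_hairpin_buckled(self, make_state):
        up = [[100, 100 + 140 * i, 0] for i in range(5)]
        down = [[110, 100 + 140 * (3 - i), 0] for i in range(4)]
        st = make_state([up + down])
        _, n, per_frame = buckling_census([shape_ratios(st)])
        assert n == 1 and per_frame[0] == 1

    def test_single_segment_never_buckled(self, make_state):
        st = make_state([[[0, 0, 0], [0, 140, 0]]])
        assert list(shape_ratios(st).values()) == [pytest.approx(1.0)]

    def test_census_counts_each_filament_once(self):
        frames = [{1: 1.0, 2: 0.55}, {1: 0.4, 2: 0.9}, {1: 0.3, 2: 0.58}]
        ever, n, per_frame = buckling_census(frames)
        assert ever == {1, 2}
        assert n == 2
        assert list(per_frame) == [1, 1, 2]

    def test_threshold_is_strict(self):
        ever, n, _ = buckling_census([{1: 0.6}])
        assert n == 0


class TestOrientation:
    def test_parallel_pair_zero_fraction(self, make_state):
        a = [[100, 100, 0], [100, 240, 0]]
        b = [[150, 100, 0], [150, 240, 0]]
        st = make_state([a, b])
        assert orientation_stats(st).antiparallel_fraction == 0.0

    def test_antiparallel_pair_full_fraction(self, make_state):
        a = [[100, 100, 0], [100, 240, 0]]
        b = [[150, 240, 0], [150, 100, 0]]
        st = make_state([a, b])
        stats_ = orientation_stats(st)
        assert stats_.antiparallel_fraction == 1.0
        assert antiparallel_fraction_y(st) == 1.0

    def test_random_isotropic_approaches_half(self, make_state, rng):
        fils = []
        for _ in range(300):
            c = np.array([rng.uniform(400, 600), rng.uniform(900, 1100), 250.0])
            az = rng.uniform(0, 2 * np.pi)
            d = np.array([np.cos(az), np.sin(az), 0.0]) * 70
            fils.append([c - d, c + d])
        st = make_state(fils)
        frac = orientation_stats(st, pair_cutoff=500.0).antiparallel_fraction
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_out_of_range_pairs_ignored(self, make_state):
        a = [[100, 100, 0], [100, 240, 0]]
        b = [[900, 1800, 0], [900, 1660, 0]]
        st = make_state([a, b])
        assert orientation_stats(st, pair_cutoff=100.0).n_pairs == 0


class TestPersistenceLength:
    def test_discrete_chain_closed_form(self):
        # <cos theta> = exp(-a/Lp) inverts exactly
        assert persistence_length(np.exp(-140 / 9000), 140.0) == \
            pytest.approx(9000.0)

    def test_rejects_degenerate_mean(self):
        with pytest.raises(ValueError):
            persistence_length(1.0, 140.0)

    def test_adjacent_cosines_of_straight_chain(self, domain):
        pts = np.array([[0, 100.0 + 140 * i, 0] for i in range(5)])
        assert np.allclose(adjacent_tangent_cosines(pts, domain), 1.0)
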