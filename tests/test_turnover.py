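import numpy as np
import pytest
from scipy import stats

from actomyo.params import Domain, ParameterSet
from actomyo.state import CrossLinker, SimulationState, Filament
from actomyo.turnover import (OrientationSpec, TurnoverConfig, assemble_network,
                              depoly_rate, nucleation_events, nucleation_rate,
                              treadmill_events)


def turnover_state(n_filaments=5, n_segments=11, pool_segments=50, seed=0,
                   k_turnover=3120.0, xi=0.0):
    # default 3120 monomers/s = 60 segment events/s: fast-traffic regime
    # for exercising the stochastic machinery
    p = ParameterSet(k_turnover=k_turnover, xi_depoly=xi)
    domain = Domain()
    fils = []
    rng = np.random.default_rng(seed)
    for i in range(n_filaments):
        x = 200.0 + 300.0 * i
        y0 = rng.uniform(0, domain.size_y)
        pts = np.array([[x, (y0 + j * p.r0_actin) % domain.size_y, 250.0]
                        for j in range(n_segments + 1)])
        fils.append(Filament(pts))
    return SimulationState(domain=domain, params=p, filaments=fils, acps=[],
                           motors=[], monomer_pool=pool_segments * 52,
                           free_acp=0, free_motor=0,
                           rng=np.random.default_rng(seed + 1))


class TestDepolyRate:
    @pytest.mark.parametrize("k0,xi,occupied,expected", [
        (60.0, 0.0, True, 60.0),    # no inhibition
        (60.0, 1.0, True, 0.0),     # complete inhibition
        (60.0, 0.6, True, 24.0),
        (60.0, 0.6, False, 60.0),   # unoccupied segments always at k0
    ])
    def test_closed_form(self, k0, xi, occupied, expected):
        assert depoly_rate(k0, xi, occupied) == pytest.approx(expected)

    def test_rejects_xi_out_of_range(self):
        with pytest.raises(ValueError):
            depoly_rate(60.0, 1.5, True)


class TestTreadmilling:
    def test_mass_conserved_over_many_events(self):
        st = turnover_state(n_filaments=20, pool_segments=200, seed=2)
        total = st.total_monomers
        events = 0
        for i in range(35000):
            before = {f.uid: f.n_segments for f in st.filaments}
            treadmill_events(st, 1.5e-3)
            nucleation_events(st, 1.5e-3)
            events += sum(abs(f.n_segments - before.get(f.uid, 0))
                          for f in st.filaments)
            if i % 1000 == 0:
                assert st.total_monomers == total
        assert st.total_monomers == total
        assert events > 10 ** 5   # heavy turnover traffic really happened

    def test_no_rate_no_change(self):
        st = turnover_state(k_turnover=0.0)
        before = [f.n_segments for f in st.filaments]
        for _ in range(100):
            treadmill_events(st, 1.5e-3, TurnoverConfig(k_turnover=0.0))
        assert [f.n_segments for f in st.filaments] == before

    def test_empty_pool_blocks_polymerization(self):
        st = turnover_state(pool_segments=0, xi=1.0)
        # occupy every pointed end so depolymerization is fully inhibited
        for f in st.filaments:
            acp = CrossLinker(f.points[0] + [0, 0, 25.0])
            st.acps.append(acp)
            st.bind_site((f, 0, 3), "acp", acp, 0)
        before = [f.n_segments for f in st.filaments]
        for _ in range(2000):
            treadmill_events(st, 1.5e-3)
        assert [f.n_segments for f in st.filaments] == before

    def test_full_inhibition_lengths_nondecreasing(self):
        st = turnover_state(xi=1.0, pool_segments=500)
        for f in st.filaments:
            acp = CrossLinker(f.points[0] + [0, 0, 25.0])
            st.acps.append(acp)
            st.bind_site((f, 0, 3), "acp", acp, 0)
        lengths = {f.uid: f.n_segments for f in st.filaments}
        for _ in range(3000):
            treadmill_events(st, 1.5e-3)
            for f in st.filaments:
                assert f.n_segments >= lengths[f.uid]
                lengths[f.uid] = f.n_segments
                # the protecting ACP must still sit on the pointed segment
                assert any(seg == 0 for seg, _ in f.occupancy)

    def test_balanced_rates_zero_mean_drift(self):
        # long filaments so no filament dies (death would bias the mean up)
        st = turnover_state(n_filaments=100, n_segments=40,
                            pool_segments=8000, seed=5)
        before = np.mean([f.n_segments for f in st.filaments])
        n_pass, p_event = 200, -np.expm1(-60.0 * 1.5e-3)
        for _ in range(n_pass):
            treadmill_events(st, 1.5e-3)
        assert len(st.filaments) == 100
        after = np.mean([f.n_segments for f in st.filaments])
        # three-sigma band of the balanced birth-death random walk
        sigma = np.sqrt(2 * n_pass * p_event / 100)
        assert abs(after - before) < 3 * sigma

    def test_depoly_releases_bound_arms(self):
        st = turnover_state(n_filaments=1, k_turnover=500.0 * 52, xi=0.0, seed=3)
        fil = st.filaments[0]
        acp = CrossLinker(fil.points[0] + [0, 0, 25.0])
        st.acps.append(acp)
        st.bind_site((fil, 0, 3), "acp", acp, 0)
        for _ in range(500):
            treadmill_events(st, 1.5e-3)
            if acp.sites[0] is None:
                break
        assert acp.sites[0] is None          # forced release happened
        assert acp not in st.acps            # fully unbound -> back to pool
        assert st.free_acp == 1


class TestNucleationController:
    def test_setpoint_baseline(self):
        st = turnover_state()
        cfg = TurnoverConfig(k_turnover=60.0)
        st.filaments = st.filaments[:3]
        # at the setpoint (11 segments ~ 1540 nm < 1560 target) rate is zero
        assert nucleation_rate(st, cfg) == 0.0

    def test_bootstrap_without_filaments(self):
        st = turnover_state(n_filaments=1)
        st.filaments.clear()
        cfg = TurnoverConfig()
        assert nucleation_rate(st, cfg) == cfg.bootstrap_rate

    def test_controller_holds_mean_length(self):
        st = turnover_state(n_filaments=20, n_segments=11, pool_segments=100,
                            seed=8)
        cfg = TurnoverConfig(k_turnover=60.0, xi_depoly=0.0)
        target = cfg.target_length
        means = []
        for i in range(20000):   # 30 s of model time at dt_k = 1.5 ms
            treadmill_events(st, 1.5e-3, cfg)
            nucleation_events(st, 1.5e-3, cfg)
            if i % 200 == 0:
                means.append(st.mean_filament_length())
        late = np.array(means[len(means) // 3:])
        assert np.all(np.abs(late / target - 1.0) < 0.15)

    def test_nuclei_point_along_y(self):
        st = turnover_state(n_filaments=3, pool_segments=100)
        cfg = TurnoverConfig(bootstrap_rate=1e9)
        st.filaments.clear()
        nucleation_events(st, 1.5e-3, cfg)
        assert len(st.filaments) == 1
        d = st.filaments[0].segment_unit(0, st.domain)
        assert abs(d[1]) == pytest.approx(1.0)


class TestOrientationSpec:
    @pytest.mark.parametrize("mode", ["isotropic", "+x", "+y", "+x/+y",
                                      "+x/±y", "±x/+y", "diagonal",
                                      "horizontal/vertical"])
    def test_samples_fall_in_declared_range(self, mode, rng):
        spec = OrientationSpec(mode)
        for _ in range(200):
            assert spec.contains(spec.sample_azimuth(rng))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            OrientationSpec("sideways")


class TestAssembly:
    def test_zero_actin_gives_empty_network(self):
        p = ParameterSet(ca_uM=0.0, r_motor=0.0, r_acp=0.0)
        st = assemble_network(p, Domain(1000, 2000, 150), seed=0,
                              assembly_time=0.0)
        assert st.filaments == []

    def test_deterministic_given_seed(self):
        kw = dict(seed=42, assembly_time=0.05)
        p = ParameterSet(r_acp=0.01, r_motor=0.02)
        d = Domain(1000, 2000, 150)
        s1 = assemble_network(p, d, "isotropic", **kw)
        s2 = assemble_network(p, d, "isotropic", **kw)
        for f1, f2 in zip(s1.filaments, s2.filaments):
            assert np.array_equal(f1.points, f2.points)
        assert len(s1.acps) == len(s2.acps)
        for a1, a2 in zip(s1.acps, s2.acps):
            assert np.array_equal(a1.hinge, a2.hinge)

    def test_isotropic_orientation_histogram_uniform(self):
        p = ParameterSet(r_motor=0.0, r_acp=0.0)
        st = assemble_network(p, Domain(2000, 4000, 500), "isotropic",
                              seed=7, assembly_time=0.0)
        az = np.array(st.meta["assembly"]["azimuths"])
        counts, _ = np.histogram(az % (2 * np.pi), bins=8, range=(0, 2 * np.pi))
        assert stats.chisquare(counts).pvalue > 0.01
        # grown orientations have no net direction (wall folds are symmetric)
        ors = np.array([f.orientation(st.domain) for f in st.filaments])
        assert np.linalg.norm(ors.mean(axis=0)) < 0.15

    def test_plus_y_bias_has_no_y_antiparallel_pairs(self):
        from actomyo.observables import antiparallel_fraction_y

        p = ParameterSet(r_motor=0.0, r_acp=0.0)
        st = assemble_network(p, Domain(2000, 4000, 500), "+y", seed=3,
                              assembly_time=0.0)
        for f in st.filaments:
            assert f.orientation(st.domain)[1] > 0
        frac = antiparallel_fraction_y(st, pair_cutoff=400.0)
        assert frac == 0.0 or np.isnan(frac)

    def test_mean_filament_length_near_reference(self):
        p = ParameterSet(r_motor=0.0, r_acp=0.0)
        st = assemble_network(p, Domain(2000, 4000, 500), seed=11,
                              assembly_time=0.0)
        assert st.mean_filament_length() == pytest.approx(1560.0, rel=0.12)

    def test_actin_mass_matches_budget(self):
        p = ParameterSet(r_motor=0.0, r_acp=0.0)
        d = Domain(1000, 2000, 150)
        st = assemble_network(p, d, seed=1, assembly_time=0.0)
        assert st.total_monomers == p.monomer_budget(d)
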