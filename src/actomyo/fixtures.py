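"""Deterministic miniature states for tests, examples, and calibration.

Available fixtures:

free_filament     one 1.56-um filament (11 segments), nothing else
motor_on_track    a filament along +y with one motor ensemble, arm 0 bound
acp_bridge        two parallel filaments bridged by one cross-linker
contractile_unit  an antiparallel filament pair with a motor in the overlap
                  (a minimal sarcomere-like contractile element)
mini_network      a 1 x 2 x 0.25 um network at reference densities
"""
from __future__ import annotations

import numpy as np

from .params import Domain, ParameterSet
from .state import CrossLinker, Filament, MotorEnsemble, SimulationState

FIXTURE_NAMES = ("free_filament", "motor_on_track", "acp_bridge",
                 "contractile_unit", "mini_network")


def _empty_state(params, domain, seed, filaments, acps=(), motors=()):
    mps = params.monomers_per_segment
    poly = sum(f.n_segments for f in filaments) * mps
    return SimulationState(domain=domain, params=params,
                           filaments=list(filaments), acps=list(acps),
                           motors=list(motors), monomer_pool=0, free_acp=0,
                           free_motor=0, time=0.0,
                           rng=np.random.default_rng(seed),
                           meta={"polymerized": poly})


def _straight_filament(origin, direction, n_segments, r0):
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return Filament(np.asarray(origin, float)[None, :]
                    + np.arange(n_segments + 1)[:, None] * r0 * d[None, :])


def make_fixture(name: str, seed: int = 0,
                 params: ParameterSet | None = None) -> SimulationState:
    p = params or ParameterSet()
    if name == "free_filament":
        domain = Domain()
        n = max(1, int(round(p.target_filament_length / p.r0_actin)))
        fil = _straight_filament(
            [domain.size_x / 2, domain.size_y / 2 - n * p.r0_actin / 2,
             domain.size_z / 2], [0, 1, 0], n, p.r0_actin)
        return _empty_state(p, domain, seed, [fil])

    if name == "motor_on_track":
        domain = Domain(size_x=1000.0, size_y=4000.0, size_z=500.0)
        n = 11
        fil = _straight_filament([500.0, 1000.0, 250.0], [0, 1, 0], n, p.r0_actin)
        backbone_y = 1000.0 + n * p.r0_actin / 2 - 1.5 * p.r0_motor_backbone
        pts = np.array([[500.0 + p.r0_motor_trans, backbone_y + i * p.r0_motor_backbone, 250.0]
                        for i in range(4)])
        motor = MotorEnsemble(pts, n_arms=p.n_arms)
        st = _empty_state(p, domain, seed, [fil], motors=[motor])
        seg = n // 2
        st.bind_site((fil, seg, 0), "motor", motor, 0)
        return st

    if name == "acp_bridge":
        domain = Domain(size_x=1000.0, size_y=4000.0, size_z=500.0)
        gap = 2 * p.r0_acp  # center-to-center spacing bridged by the ACP
        f1 = _straight_filament([500.0 - gap / 2, 1000.0, 250.0], [0, 1, 0], 6, p.r0_actin)
        f2 = _straight_filament([500.0 + gap / 2, 1000.0, 250.0], [0, 1, 0], 6, p.r0_actin)
        acp = CrossLinker([500.0, 1000.0 + 3 * p.r0_actin, 250.0])
        st = _empty_state(p, domain, seed, [f1, f2], acps=[acp])
        st.bind_site((f1, 3, 0), "acp", acp, 0)
        st.bind_site((f2, 3, 0), "acp", acp, 1)
        return st

    if name == "contractile_unit":
        # sarcomere-like antiparallel pair: pointed ends overlap at the
        # center, barbed ends point outward, motor in the overlap.  Walking
        # toward the barbed ends slides the pair together (contraction).
        domain = Domain(size_x=1000.0, size_y=6000.0, size_z=500.0)
        n = 8
        overlap = 4 * p.r0_actin
        y0 = 3000.0
        fa = _straight_filament([500.0 - 20.0, y0 + overlap / 2, 250.0],
                                [0, -1, 0], n, p.r0_actin)   # barbed down
        fb = _straight_filament([500.0 + 20.0, y0 - overlap / 2, 250.0],
                                [0, 1, 0], n, p.r0_actin)    # barbed up
        pts = np.array([[500.0, y0 - 1.5 * p.r0_motor_backbone + i * p.r0_motor_backbone,
                         250.0 + p.r0_motor_trans] for i in range(4)])
        motor = MotorEnsemble(pts, n_arms=p.n_arms)
        st = _empty_state(p, domain, seed, [fa, fb], motors=[motor])
        # one arm per filament, bound next to its anchor inside the overlap
        st.bind_site((fa, 1, 11), "motor", motor, p.n_arms // 2)  # anchor end 3
        st.bind_site((fb, 1, 11), "motor", motor, 0)              # anchor end 0
        return st

    if name == "mini_network":
        from .turnover import assemble_network

        domain = Domain(size_x=1000.0, size_y=2000.0, size_z=250.0)
        return assemble_network(p, domain, "isotropic", seed=seed,
                                assembly_time=0.3)

    raise ValueError(f"unknown fixture {name!r}; valid names: {FIXTURE_NAMES}")
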