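"""Actin turnover (treadmilling) and network self-assembly.

Treadmilling imposes equal polymerization and reference depolymerization
rates at the barbed and pointed ends.  Depolymerization of a pointed-end
segment that carries a bound ACP or motor arm is inhibited by the factor
(1 - xi): xi = 0 means no inhibition, xi = 1 complete inhibition.  A
proportional controller adjusts the nucleation rate to hold the mean
filament length near its target; new nuclei appear as single segments
oriented along +/-y near existing actin.

Assembly grows filaments by direct sampling of the equilibrium joint-angle
distribution (Boltzmann-weighted bending), places motor ensembles, and then
runs a short dynamic phase in which ACP and motor arms bind while motor
walking is disabled; the clock is reset to zero when walking starts.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np

from .params import Domain, ParameterSet
from .state import CrossLinker, Filament, MotorEnsemble, SimulationState

TWO_PI = 2.0 * math.pi

_PRESETS = {
    "isotropic": [(0.0, TWO_PI)],
    "+x": [(-math.pi / 12, math.pi / 12)],
    "+y": [(math.pi / 2 - math.pi / 12, math.pi / 2 + math.pi / 12)],
    "+x/+y": [(0.0, math.pi / 2)],
    "+x/±y": [(-math.pi / 2, math.pi / 2)],
    "±x/+y": [(0.0, math.pi)],
    "diagonal": [(math.pi / 4 - math.pi / 12, math.pi / 4 + math.pi / 12),
                 (5 * math.pi / 4 - math.pi / 12, 5 * math.pi / 4 + math.pi / 12)],
    "horizontal/vertical": [(a - math.pi / 36, a + math.pi / 36)
                            for a in (0.0, math.pi / 2, math.pi, 3 * math.pi / 2)],
}
# ascii aliases
_PRESETS["+x/+-y"] = _PRESETS["+x/±y"]
_PRESETS["+-x/+y"] = _PRESETS["±x/+y"]


@dataclasses.dataclass
class OrientationSpec:
    """Angular ranges (azimuth in the x-y plane, radians from +x) from which
    the barbed-end direction of nucleated filaments is drawn."""

    mode: str = "isotropic"
    intervals: list = None

    def __post_init__(self):
        if self.intervals is None:
            if self.mode not in _PRESETS:
                raise ValueError(f"unknown orientation mode {self.mode!r}; "
                                 f"choose from {sorted(_PRESETS)}")
            self.intervals = list(_PRESETS[self.mode])

    def sample_azimuth(self, rng: np.random.Generator) -> float:
        widths = np.array([hi - lo for lo, hi in self.intervals])
        k = int(rng.choice(len(self.intervals), p=widths / widths.sum()))
        lo, hi = self.intervals[k]
        return float(rng.uniform(lo, hi)) % TWO_PI

    def contains(self, azimuth: float) -> bool:
        az = azimuth % TWO_PI
        for lo, hi in self.intervals:
            if lo <= az <= hi or lo <= az - TWO_PI <= hi or lo <= az + TWO_PI <= hi:
                return True
        return False

    @classmethod
    def coerce(cls, spec) -> "OrientationSpec":
        return spec if isinstance(spec, cls) else cls(mode=spec)


@dataclasses.dataclass
class TurnoverConfig:
    """Treadmilling configuration.

    ``k_turnover`` is in monomers per second at each filament end (the
    physiological 30-120 1/s range); one polymerization/depolymerization
    event adds or removes a whole 52-monomer segment, so segment events
    occur at k_turnover / monomers_per_segment.
    """

    k_turnover: float = 60.0          # monomers/s, polymerization = reference depoly
    xi_depoly: float = 0.0            # inhibition factor in [0, 1]
    target_length: float = 1560.0     # nm
    # proportional gain; high enough to offset the death of young nuclei
    controller_gain: float = 4.0
    bootstrap_rate: float = 1.0       # 1/s nucleation when no filaments exist

    @classmethod
    def from_params(cls, p: ParameterSet) -> "TurnoverConfig":
        return cls(k_turnover=p.k_turnover, xi_depoly=p.xi_depoly,
                   target_length=p.target_filament_length)


def depoly_rate(k0: float, xi: float, pointed_segment_occupied: bool) -> float:
    """Adjusted depolymerization rate: k0 * (1 - xi) when the leaving segment
    carries a bound arm, k0 otherwise."""
    if not 0.0 <= xi <= 1.0:
        raise ValueError("xi must lie in [0, 1]")
    return k0 * (1.0 - xi) if pointed_segment_occupied else k0


def _prob(rate: float, dt: float) -> float:
    return -math.expm1(-rate * dt)


def _grow_point(state: SimulationState, fil: Filament) -> np.ndarray:
    """Next barbed-end point continuing the terminal segment direction."""
    p = state.params
    d = fil.segment_unit(fil.n_segments - 1, state.domain) * p.r0_actin
    new = fil.points[-1] + d
    # reflect at the x/z walls so growth stays inside
    for axis, size in ((0, state.domain.size_x), (2, state.domain.size_z)):
        if new[axis] < 0 or new[axis] > size:
            d[axis] = -d[axis]
            new = fil.points[-1] + d
    new[1] %= state.domain.size_y
    return new


def treadmill_events(state: SimulationState, dt: float,
                     cfg: TurnoverConfig | None = None) -> bool:
    """One interval of polymerization/depolymerization on every filament."""
    p = state.params
    cfg = cfg or TurnoverConfig.from_params(p)
    rng = state.rng
    mps = p.monomers_per_segment
    changed = False
    k_seg = cfg.k_turnover / mps      # segment-event rate per end
    p_poly = _prob(k_seg, dt)
    for fil in list(state.filaments):
        # barbed-end polymerization, limited by the monomer pool
        if state.monomer_pool >= mps and rng.random() < p_poly:
            new = _grow_point(state, fil)
            fil.points = np.vstack([fil.points, new])
            state.monomer_pool -= mps
            changed = True
        # pointed-end depolymerization, inhibited by bound arms
        occupied = any(seg == 0 for seg, _ in fil.occupancy)
        k_d = depoly_rate(k_seg, cfg.xi_depoly, occupied)
        if k_d > 0 and rng.random() < _prob(k_d, dt):
            state.release_arms_on_segment(fil, 0)
            fil.points = fil.points[1:]
            fil.occupancy = {(s - 1, i): v for (s, i), v in fil.occupancy.items()}
            for (s, i), (kind, owner, arm) in fil.occupancy.items():
                site = (fil, s, i)
                if kind == "acp":
                    owner.sites[arm] = site
                else:
                    owner.arm_site[arm] = site
            state.monomer_pool += mps
            changed = True
            if fil.n_segments == 0:
                state.filaments.remove(fil)
    return changed


def nucleation_rate(state: SimulationState, cfg: TurnoverConfig) -> float:
    """Proportional controller on the mean filament length.

    Nucleating short filaments lowers the mean length, so the rate rises
    when the current mean exceeds the target and is zero below it.
    """
    if not state.filaments:
        return cfg.bootstrap_rate
    excess = state.mean_filament_length() / cfg.target_length - 1.0
    n = len(state.filaments)
    k_seg = cfg.k_turnover / state.params.monomers_per_segment
    return cfg.controller_gain * n * k_seg * max(0.0, excess)


def nucleation_events(state: SimulationState, dt: float,
                      cfg: TurnoverConfig | None = None) -> bool:
    """Spawn single-segment nuclei oriented along +/-y near existing actin."""
    p = state.params
    cfg = cfg or TurnoverConfig.from_params(p)
    rng = state.rng
    mps = p.monomers_per_segment
    if state.monomer_pool < mps:
        return False
    rate = nucleation_rate(state, cfg)
    if rate <= 0 or rng.random() >= _prob(rate, dt):
        return False
    if state.filaments:
        fil = state.filaments[int(rng.integers(len(state.filaments)))]
        seg = int(rng.integers(fil.n_segments))
        base = 0.5 * (fil.points[seg] + fil.points[seg + 1])
        base = base + rng.normal(scale=50.0, size=3)
    else:
        base = rng.uniform(0, 1, size=3) * state.domain.size
    base[0] = np.clip(base[0], 10.0, state.domain.size_x - 10.0)
    base[2] = np.clip(base[2], 10.0, state.domain.size_z - 10.0)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    tip = base + np.array([0.0, sign * p.r0_actin, 0.0])
    pts = state.domain.wrap_y(np.array([base, tip]))
    state.filaments.append(Filament(pts, created=state.time))
    state.monomer_pool -= mps
    return True


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

def _sample_filament_points(rng, n_segments, origin, azimuth, p: ParameterSet,
                            domain: Domain):
    """Grow a filament from the equilibrium Boltzmann bend distribution.

    Each joint angle theta is drawn from P(theta) ~ exp(-kb theta^2 / 2kBT)
    sin(theta) (sampled in the Gaussian small-angle regime appropriate for
    kb >> kBT), azimuth uniform about the previous axis; bond lengths are
    r0 + N(0, kBT/ks).  Directions reflect at the x/z walls.
    """
    pts = [np.asarray(origin, dtype=float)]
    d = np.array([math.cos(azimuth), math.sin(azimuth), 0.0])
    sigma_th = math.sqrt(p.kBT / p.kb_actin)
    sigma_r = math.sqrt(p.kBT / p.ks_actin) if p.ks_actin > 0 else 0.0
    for _ in range(n_segments):
        r = p.r0_actin + sigma_r * rng.normal()
        new = pts[-1] + r * d
        for axis, size in ((0, domain.size_x), (2, domain.size_z)):
            if new[axis] < 0 or new[axis] > size:
                d[axis] = -d[axis]
                new = pts[-1] + r * d
        pts.append(new)
        # bend: polar angle Rayleigh(sigma_th), the 2D Gaussian tilt magnitude
        theta = sigma_th * math.sqrt(2.0 * rng.exponential(1.0))
        phi = rng.uniform(0, TWO_PI)
        d = _rotate_about_perp(d, theta, phi)
    return np.array(pts)


def _rotate_about_perp(d, theta, phi):
    """Tilt unit vector d by polar angle theta, azimuth phi about d."""
    # build an orthonormal frame around d
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    out = (math.cos(theta) * d
           + math.sin(theta) * (math.cos(phi) * e1 + math.sin(phi) * e2))
    return out / np.linalg.norm(out)


def _sample_lengths(rng, n_segments_budget: int, target: int):
    """Per-filament segment counts, roughly exponential around the target
    mean, consuming the whole budget."""
    lengths = []
    remaining = n_segments_budget
    while remaining >= 2:
        n = int(np.clip(round(rng.exponential(target)), 2, 3 * target))
        n = min(n, remaining)
        if remaining - n == 1:
            n += 1
        lengths.append(n)
        remaining -= n
    return lengths, remaining


def assemble_network(params: ParameterSet, domain: Domain,
                     orientation="isotropic", seed: int = 0,
                     assembly_time: float = 0.5,
                     kinetics_interval: int = 20,
                     max_binding_passes: int | None = None) -> SimulationState:
    """Self-assemble a homogeneous actomyosin network.

    Consumes the actin/ACP/motor budgets implied by C_A, R_ACP and R_M,
    grows filaments along the requested orientation spec, places motor
    ensembles, and runs ``assembly_time`` seconds of thermal dynamics with
    binding on and motor walking off.  Returns the state with time reset to
    zero (motors start walking at t = 0).
    """
    spec = OrientationSpec.coerce(orientation)
    rng = np.random.default_rng(seed)
    p = params
    n_mono = p.monomer_budget(domain)
    mps = p.monomers_per_segment
    n_seg_budget = n_mono // mps
    if p.ca_uM > 0 and n_seg_budget < 1:
        raise ValueError("actin budget too small for a single segment; "
                         "increase C_A or the domain volume")

    state = SimulationState(domain=domain, params=p, filaments=[], acps=[],
                            motors=[], monomer_pool=n_mono, free_acp=0,
                            free_motor=0, time=0.0, rng=rng)
    azimuths = []
    if n_seg_budget >= 1 and p.ca_uM > 0:
        target = p.segments_per_filament_target
        lengths, leftover = _sample_lengths(rng, n_seg_budget, target)
        margin = 20.0
        for n_seg in lengths:
            origin = np.array([
                rng.uniform(margin, domain.size_x - margin),
                rng.uniform(0.0, domain.size_y),
                rng.uniform(min(margin, domain.size_z / 4),
                            domain.size_z - min(margin, domain.size_z / 4)),
            ])
            az = spec.sample_azimuth(rng)
            azimuths.append(az)
            pts = _sample_filament_points(rng, n_seg, origin, az, p, domain)
            state.filaments.append(Filament(domain.wrap_y(pts)))
            state.monomer_pool -= n_seg * mps

    # budgets for cross-linkers and motors (molecules per actin monomer)
    state.free_acp = int(round(p.r_acp * n_mono))
    n_ensembles = int(round(p.r_motor * n_mono / p.molecules_per_ensemble))
    for _ in range(n_ensembles):
        center = np.array([rng.uniform(0, domain.size_x),
                           rng.uniform(0, domain.size_y),
                           rng.uniform(0, domain.size_z)])
        az = rng.uniform(0, TWO_PI)
        d = np.array([math.cos(az), math.sin(az), 0.0])
        offs = (np.arange(4) - 1.5)[:, None] * p.r0_motor_backbone * d[None, :]
        pts = center[None, :] + offs
        lo, hi = pts[:, 0].min(), pts[:, 0].max()
        if lo < 0:
            pts[:, 0] -= lo - 5.0
        if hi > domain.size_x:
            pts[:, 0] -= hi - domain.size_x + 5.0
        pts[:, 2] = np.clip(pts[:, 2], 5.0, domain.size_z - 5.0)
        state.motors.append(MotorEnsemble(domain.wrap_y(pts), n_arms=p.n_arms))

    # dynamic binding phase: thermal motion on, motor walking off
    if assembly_time > 0 and state.filaments:
        from .integrator import StepSchedule, run

        schedule = StepSchedule(dt=p.dt, duration=assembly_time,
                                kinetics_interval=kinetics_interval,
                                record_interval=0)
        run(state, schedule, walking=False, turnover=False)

    state.time = 0.0
    state.meta["assembly"] = {
        "n_filaments": len(state.filaments),
        "n_segments": sum(f.n_segments for f in state.filaments),
        "mean_filament_length_nm": state.mean_filament_length(),
        "n_acp_bound": len(state.acps),
        "n_crosslinks": state.n_crosslinks,
        "n_motors": len(state.motors),
        "n_bound_motor_arms": state.n_bound_motor_arms(),
        "monomer_pool": state.monomer_pool,
        "seed": seed,
        "orientation": spec.mode,
        "azimuths": azimuths,
    }
    state.validate()
    return state
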