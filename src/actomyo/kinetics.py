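"""Stochastic binding, unbinding, and walking of cross-linkers and motors.

Cross-linkers (ACPs) follow a Bell slip bond: the unbinding rate grows
exponentially with the extensional force on a stretched arm and stays at the
zero-force rate when the arm is compressed.  Motor arms are catch bonds:
under resisting load (opposing motion toward the barbed end) both the
walking and unbinding rates fall, the walking rate reaching zero at the
stall force; under assisting load beyond a small threshold the arm releases
immediately.  The functional form of the catch bond is a calibrated
single-exponential stand-in anchored to the unloaded velocity (140 nm/s),
the stall force (5.7 pN), and the zero-load unbinding rate (0.049 1/s); a
tabulated force-rate model can be plugged in instead.

All events are sampled per kinetics interval with probability
1 - exp(-k * dt); the stated rates satisfy k * dt << 1 at the reference
time step.  The per-interval pass is vectorized over arms and candidate
sites for speed; the scalar rate functions remain the unit-level contract.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from .geometry import minimum_image
from .params import ParameterSet


@dataclasses.dataclass
class MotorRateModel:
    """Force-dependent walking and unbinding rates of one motor arm."""

    f_stall: float = 5.7        # pN
    v0: float = 140.0           # nm/s
    step: float = 7.0           # nm
    k_ub0: float = 0.049        # 1/s
    lambda_catch: float = 1.0   # nm
    kBT: float = 4.114          # pN nm
    f_release_assist: float = 4.0  # pN
    k_bind: float = 320.0       # 1/s per arm (40 per head * 8 heads)
    n_heads: int = 8
    # optional tabulated (F, k_w, k_u) override for resisting loads
    table_f: Optional[np.ndarray] = None
    table_kw: Optional[np.ndarray] = None
    table_ku: Optional[np.ndarray] = None

    @property
    def k_walk0(self) -> float:
        return self.v0 / self.step

    @classmethod
    def from_params(cls, p: ParameterSet) -> "MotorRateModel":
        return cls(f_stall=p.f_stall, v0=p.v_unloaded, step=p.step_size,
                   k_ub0=p.k_ub0_motor, lambda_catch=p.lambda_motor,
                   kBT=p.kBT, f_release_assist=p.f_release_assist,
                   k_bind=p.k_bind_motor, n_heads=p.n_heads)

    @classmethod
    def modified(cls, p: ParameterSet) -> "MotorRateModel":
        """Lower-duty-ratio motor variant: stall 5.3 pN, unbinding 0.49 1/s."""
        m = cls.from_params(p)
        m.f_stall = 5.3
        m.k_ub0 = 0.49
        return m

    @classmethod
    def from_table(cls, f, k_w, k_u, **kwargs) -> "MotorRateModel":
        m = cls(**kwargs)
        m.table_f = np.asarray(f, dtype=float)
        m.table_kw = np.asarray(k_w, dtype=float)
        m.table_ku = np.asarray(k_u, dtype=float)
        return m


def motor_rates(f_parallel: float, model: MotorRateModel):
    """(k_walk, k_unbind) of a bound arm at longitudinal load ``f_parallel``.

    ``f_parallel`` is the longitudinal-spring force projected on the
    barbed-end direction of the track: positive values resist walking.
    Assisting loads beyond the release threshold detach the arm immediately
    (k_unbind = inf).
    """
    if f_parallel < -model.f_release_assist:
        return 0.0, math.inf
    f = max(0.0, f_parallel)
    if model.table_f is not None:
        k_w = float(np.interp(f, model.table_f, model.table_kw))
        k_u = float(np.interp(f, model.table_f, model.table_ku))
        return k_w, k_u
    k_w = model.k_walk0 * max(0.0, 1.0 - f / model.f_stall)
    k_u = model.k_ub0 * math.exp(-model.lambda_catch * min(f, model.f_stall) / model.kBT)
    return k_w, k_u


def motor_rates_vec(f_parallel: np.ndarray, model: MotorRateModel):
    """Vectorized :func:`motor_rates`; release encoded as k_unbind = inf."""
    f_parallel = np.asarray(f_parallel, dtype=float)
    f = np.clip(f_parallel, 0.0, None)
    if model.table_f is not None:
        k_w = np.interp(f, model.table_f, model.table_kw)
        k_u = np.interp(f, model.table_f, model.table_ku)
    else:
        k_w = model.k_walk0 * np.clip(1.0 - f / model.f_stall, 0.0, None)
        k_u = model.k_ub0 * np.exp(-model.lambda_catch
                                   * np.minimum(f, model.f_stall) / model.kBT)
    release = f_parallel < -model.f_release_assist
    k_w = np.where(release, 0.0, k_w)
    k_u = np.where(release, np.inf, k_u)
    return k_w, k_u


def acp_unbind_rate(force: float, r: float, p: ParameterSet) -> float:
    """Bell slip-bond unbinding rate of one ACP arm.

    ``force`` is |F_s| = ks * |r - r0|; the force-accelerated branch applies
    only to stretched arms (r >= r0), compressed arms unbind at the
    zero-force rate.
    """
    if force < 0:
        raise ValueError("force magnitude must be >= 0")
    if r >= p.r0_acp:
        return p.k_ub0_acp * math.exp(p.lambda_acp * force / p.kBT)
    return p.k_ub0_acp


def event_prob(rate: float, dt: float) -> float:
    """Probability of at least one event in dt: 1 - exp(-k dt)."""
    if rate == math.inf:
        return 1.0
    return -math.expm1(-rate * dt)


# ---------------------------------------------------------------------------
# arm force evaluation (scalar contract, used by tests and observables)
# ---------------------------------------------------------------------------

def acp_arm_geometry(state, acp, arm: int):
    """(force magnitude, arm length) of one bound ACP arm."""
    fil, seg, idx = acp.sites[arm]
    att = fil.site_position(seg, idx, state.params)
    r = float(np.linalg.norm(minimum_image(acp.hinge, att, state.domain)))
    force = state.params.ks_acp * abs(r - state.params.r0_acp)
    return force, r


def motor_arm_parallel_force(state, motor, arm: int) -> float:
    """Longitudinal-spring force component toward the barbed end (pN).

    Positive when the binding point leads the backbone anchor toward the
    barbed end (the walking direction), i.e. a resisting load on the arm.
    """
    fil, seg, idx = motor.arm_site[arm]
    p = state.params
    att = fil.site_position(seg, idx, p)
    t_hat = fil.segment_unit(seg, state.domain)
    d = minimum_image(motor.anchor_point(arm), att, state.domain)
    return p.ks_motor_long * float(d @ t_hat)


def _next_site_toward_barbed(fil, seg: int, idx: int, sites_per_segment: int):
    idx += 1
    if idx >= sites_per_segment:
        seg += 1
        idx = 0
    if seg >= fil.n_segments:
        return None  # barbed-end terminal: blocked
    return seg, idx


# ---------------------------------------------------------------------------
# per-interval kinetics pass (vectorized)
# ---------------------------------------------------------------------------

def _mi_y(d: np.ndarray, ly: float) -> np.ndarray:
    d[..., 1] -= ly * np.round(d[..., 1] / ly)
    return d


def kinetics_pass(state, dt_k: float, model: Optional[MotorRateModel] = None,
                  walking: bool = True, binding: bool = True,
                  turnover: bool = True, system=None) -> bool:
    """Execute one interval of stochastic events.

    Returns True when the interaction *topology* changed (bind/unbind/
    turnover); pure walking moves are applied to ``system`` in place when a
    flattened system is supplied.
    """
    p = state.params
    rng = state.rng
    if model is None:
        model = state.meta.get("motor_model") or MotorRateModel.from_params(p)
    if system is None:
        from .flatten import build_system

        system = build_system(state)
    P = system.P
    ly = state.domain.size_y
    off = {id(f): system.fil_offsets[k] for k, f in enumerate(state.filaments)}
    sps = p.sites_per_segment
    changed = False

    # --- ACP unbinding (Bell slip bond) ------------------------------------
    rows = []
    for a in state.acps:
        h = system.acp_offsets[a.uid]
        for arm in (0, 1):
            site = a.sites[arm]
            if site is not None:
                fil, seg, idx = site
                rows.append((a, arm, off[id(fil)] + seg, idx / sps, h))
    if rows:
        i0 = np.array([r[2] for r in rows])
        s = np.array([r[3] for r in rows])
        hidx = np.array([r[4] for r in rows])
        att = (1.0 - s)[:, None] * P[i0] + s[:, None] * P[i0 + 1]
        d = _mi_y(att - P[hidx], ly)
        r = np.linalg.norm(d, axis=1)
        force = p.ks_acp * np.abs(r - p.r0_acp)
        rate = np.where(r >= p.r0_acp,
                        p.k_ub0_acp * np.exp(p.lambda_acp * force / p.kBT),
                        p.k_ub0_acp)
        hits = rng.random(len(rows)) < -np.expm1(-rate * dt_k)
        for k in np.nonzero(hits)[0]:
            a, arm = rows[k][0], rows[k][1]
            state.unbind_site(a.sites[arm], "acp", a, arm)
            changed = True
        for a in [a for a in state.acps if a.n_bound == 0]:
            state.acps.remove(a)
            state.free_acp += 1

    # --- motor arm unbinding and walking -----------------------------------
    rows = []
    for m in state.motors:
        base = system.motor_offsets[m.uid]
        for arm in range(m.n_arms):
            site = m.arm_site[arm]
            if site is not None:
                fil, seg, idx = site
                rows.append((m, arm, off[id(fil)] + seg, idx / sps,
                             base + m.arm_anchor[arm]))
    if rows:
        i0 = np.array([r[2] for r in rows])
        s = np.array([r[3] for r in rows])
        anc = np.array([r[4] for r in rows])
        t = _mi_y(P[i0 + 1] - P[i0], ly)
        t /= np.linalg.norm(t, axis=1)[:, None]
        att = (1.0 - s)[:, None] * P[i0] + s[:, None] * P[i0 + 1]
        d = _mi_y(att - P[anc], ly)
        f_par = p.ks_motor_long * np.einsum("ij,ij->i", d, t)
        k_w, k_u = motor_rates_vec(f_par, model)
        u = rng.random((len(rows), 2))
        unbind = u[:, 0] < -np.expm1(-np.where(np.isinf(k_u), np.inf, k_u) * dt_k)
        unbind |= np.isinf(k_u)
        walk = walking & (~unbind) & (u[:, 1] < -np.expm1(-k_w * dt_k))
        for k in np.nonzero(unbind)[0]:
            m, arm = rows[k][0], rows[k][1]
            state.unbind_site(m.arm_site[arm], "motor", m, arm)
            changed = True
        for k in np.nonzero(walk)[0]:
            m, arm = rows[k][0], rows[k][1]
            fil, seg, idx = m.arm_site[arm]
            nxt = _next_site_toward_barbed(fil, seg, idx, sps)
            if nxt is None or nxt in fil.occupancy:
                continue  # blocked at the barbed end or by an occupied site
            state.unbind_site((fil, seg, idx), "motor", m, arm)
            state.bind_site((fil, nxt[0], nxt[1]), "motor", m, arm)
            if not changed:
                _move_arm_in_system(system, state, m, arm, off)
    # --- binding ------------------------------------------------------------
    if binding and state.filaments:
        changed |= _bind_acp_first_arms(state, dt_k, system)
        changed |= _binding_search(state, dt_k, model, system, off)

    # --- actin turnover ------------------------------------------------------
    if turnover and p.k_turnover > 0:
        from .turnover import nucleation_events, treadmill_events

        changed |= treadmill_events(state, dt_k)
        changed |= nucleation_events(state, dt_k)

    return changed


def _move_arm_in_system(system, state, motor, arm, off) -> None:
    """Update the flattened spring/axial rows of one walked motor arm."""
    key = (motor.uid, arm)
    rowmap = system.motor_arm_rows
    if key not in rowmap:
        return
    srow, arow = rowmap[key]
    fil, seg, idx = motor.arm_site[arm]
    base = off[id(fil)]
    s = idx / state.params.sites_per_segment
    system.springs_i[srow, 2] = base + seg
    system.springs_i[srow, 3] = base + seg + 1
    system.springs_f[srow, 1] = s
    system.axial_i[arow, 0] = base + seg
    system.axial_i[arow, 1] = base + seg + 1
    system.axial_f[arow, 0] = s


def _bind_acp_first_arms(state, dt_k: float, system) -> bool:
    """Implicit-pool ACPs attach a first arm at a constant rate.

    Free ACPs are carried as a well-mixed concentration, so the landing site
    is drawn uniformly over all unoccupied sites; the hinge is placed one
    arm length away in a random direction.
    """
    p = state.params
    rng = state.rng
    if state.free_acp <= 0:
        return False
    n_events = rng.binomial(state.free_acp, event_prob(p.k_bind_acp, dt_k))
    if n_events == 0:
        return False
    from .state import CrossLinker

    nb = system.actin_bonds.shape[0]
    if nb == 0:
        return False
    changed = False
    sps = p.sites_per_segment
    for _ in range(n_events):
        k = int(rng.integers(nb))
        fil = state.filaments[int(system.bond_fil[k])]
        seg = int(system.bond_seg[k])
        idx = int(rng.integers(sps))
        if (seg, idx) in fil.occupancy:
            continue  # collision: event consumed without binding
        att = fil.site_position(seg, idx, p)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        hinge = att + p.r0_acp * u
        if not (0 < hinge[0] < state.domain.size_x and 0 < hinge[2] < state.domain.size_z):
            hinge = att - p.r0_acp * u
        acp = CrossLinker(state.domain.wrap_y(hinge))
        state.acps.append(acp)
        state.bind_site((fil, seg, idx), "acp", acp, 0)
        state.free_acp -= 1
        changed = True
    return changed


def _binding_search(state, dt_k: float, model: MotorRateModel, system,
                    off) -> bool:
    """Capture-range binding of dangling ACP second arms and free motor arms.

    One vectorized searcher-by-segment distance pass narrows to nearby
    segments; per-site distances then yield candidate (arm, site) pairs,
    each of which binds with probability 1 - exp(-k dt); at most one site
    per arm is taken per interval.
    """
    p = state.params
    rng = state.rng
    P = system.P
    ly = state.domain.size_y
    bonds = system.actin_bonds
    if bonds.shape[0] == 0:
        return False

    searchers = []   # (kind, owner, arm, position, capture, prob, exclude_fil_ordinal)
    p_acp = event_prob(p.k_bind_acp, dt_k)
    p_mot = event_prob(model.k_bind, dt_k)
    fil_ord = {id(f): k for k, f in enumerate(state.filaments)}
    for a in state.acps:
        if a.n_bound == 1:
            arm = 1 if a.sites[0] is not None else 0
            bound = a.sites[0] if a.sites[0] is not None else a.sites[1]
            # ACPs born earlier in this pass are not yet in the flat system
            hinge = (P[system.acp_offsets[a.uid]]
                     if a.uid in system.acp_offsets else a.hinge)
            searchers.append(("acp", a, arm, hinge,
                              p.capture_acp, p_acp, fil_ord[id(bound[0])]))
    for m in state.motors:
        base = system.motor_offsets[m.uid]
        for arm in range(m.n_arms):
            if m.arm_site[arm] is None:
                searchers.append(("motor", m, arm, P[base + m.arm_anchor[arm]],
                                  p.capture_motor, p_mot, -1))
    if not searchers:
        return False

    pos = np.array([s[3] for s in searchers])
    capture = np.array([s[4] for s in searchers])
    starts = P[bonds[:, 0]]
    dvec = _mi_y(P[bonds[:, 1]] - starts, ly)
    mids = starts + 0.5 * dvec
    d = _mi_y(pos[:, None, :] - mids[None, :, :], ly)
    dist2 = np.einsum("ijk,ijk->ij", d, d)
    reach = capture[:, None] + 0.5 * p.r0_actin + 10.0
    si, bi = np.nonzero(dist2 < reach * reach)
    if si.size == 0:
        return False

    fracs = np.arange(p.sites_per_segment) / p.sites_per_segment
    sites = starts[bi][:, None, :] + fracs[None, :, None] * dvec[bi][:, None, :]
    dd = _mi_y(pos[si][:, None, :] - sites, ly)
    within = np.einsum("ijk,ijk->ij", dd, dd) < (capture[si] ** 2)[:, None]
    ks, js = np.nonzero(within)
    if ks.size == 0:
        return False

    changed = False
    # group candidates per searcher, preserving deterministic order
    order = np.lexsort((js, ks))
    cur = -1
    cand: list = []

    def flush(searcher_idx, cands):
        nonlocal changed
        if searcher_idx < 0 or not cands:
            return
        kind, owner, arm, _, _, prob, excl = searchers[searcher_idx]
        valid = []
        for b in cands:
            f_ord = int(system.bond_fil[b[0]])
            if kind == "acp" and f_ord == excl:
                continue
            fil = state.filaments[f_ord]
            key = (int(system.bond_seg[b[0]]), int(b[1]))
            if key not in fil.occupancy:
                valid.append((fil, key[0], key[1]))
        if not valid:
            return
        hits = np.nonzero(rng.random(len(valid)) < prob)[0]
        if hits.size:
            fil, seg, idx = valid[int(rng.choice(hits))]
            state.bind_site((fil, seg, idx), kind, owner, arm)
            changed = True

    for t in order:
        k, j = int(ks[t]), int(js[t])
        if si[k] != cur:
            flush(cur, cand)
            cur = int(si[k])
            cand = []
        cand.append((int(bi[k]), j))
    flush(cur, cand)
    return changed


# ---------------------------------------------------------------------------
# single-arm calibration protocols (load clamp)
# ---------------------------------------------------------------------------

def measure_arm_velocity(load: float, model: Optional[MotorRateModel] = None,
                         params: Optional[ParameterSet] = None,
                         duration: float = 1.0, n_replicates: int = 100,
                         seed: int = 0, dt: Optional[float] = None) -> float:
    """Mean walking velocity (nm/s) of one arm under a clamped load.

    The arm sits on a rigidly clamped track with 7-nm sites and experiences a
    constant longitudinal load, so walking and unbinding are sampled with the
    same per-interval Bernoulli scheme the network simulation uses.  Velocity
    is displacement over attached time, averaged over replicates.
    """
    p = params or ParameterSet()
    model = model or MotorRateModel.from_params(p)
    dt = dt if dt is not None else 10 * p.dt
    k_w, k_u = motor_rates(load, model)
    p_w = event_prob(k_w, dt)
    p_u = event_prob(k_u, dt)
    rng = np.random.default_rng(seed)
    nsteps = int(round(duration / dt))
    steps_taken = np.zeros(n_replicates, dtype=np.int64)
    attached = np.ones(n_replicates, dtype=bool)
    t_attached = np.zeros(n_replicates)
    for _ in range(nsteps):
        u = rng.random((n_replicates, 2))
        attached &= u[:, 0] >= p_u
        steps_taken[attached & (u[:, 1] < p_w)] += 1
        t_attached[attached] += dt
    v = model.step * steps_taken / np.maximum(t_attached, dt)
    return float(np.mean(v))


def force_velocity_curve(loads, model: Optional[MotorRateModel] = None,
                         params: Optional[ParameterSet] = None,
                         duration: float = 0.5, n_replicates: int = 100,
                         seed: int = 0):
    """Measured mean velocity at each clamped load (nm/s)."""
    return np.array([
        measure_arm_velocity(f, model=model, params=params, duration=duration,
                             n_replicates=n_replicates, seed=seed + 7 * i)
        for i, f in enumerate(loads)
    ])


def stall_force_estimate(loads=None, model: Optional[MotorRateModel] = None,
                         params: Optional[ParameterSet] = None,
                         duration: float = 0.5, n_replicates: int = 100,
                         seed: int = 0) -> float:
    """Zero-crossing load (pN) of the measured force-velocity curve.

    Fits a line through the descending branch (loads with clearly nonzero
    velocity) and returns its intercept with v = 0.
    """
    p = params or ParameterSet()
    model = model or MotorRateModel.from_params(p)
    if loads is None:
        loads = np.arange(0.0, 7.25, 0.5)
    loads = np.asarray(loads, dtype=float)
    v = force_velocity_curve(loads, model=model, params=params,
                             duration=duration, n_replicates=n_replicates,
                             seed=seed)
    mask = v > 0.05 * model.v0
    if mask.sum() < 2:
        raise RuntimeError("force-velocity curve has no descending branch")
    slope, intercept = np.polyfit(loads[mask], v[mask], 1)
    if slope >= 0:
        raise RuntimeError("force-velocity curve is not decreasing")
    return float(-intercept / slope)
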