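"""Flattened mechanical view of a simulation state.

The integrator works on a flat array of points plus interaction tables; this
module builds those tables from the object-level state and scatters updated
positions back.  Every interaction endpoint is an *attachment*: a point on
the line between two flat points, ``p = (1-s) P[i] + s P[j]``.  A plain
point is the degenerate attachment (i, i, 0).  Forces applied at an
attachment are lever-distributed onto its carriers, which reproduces the
endpoint redistribution rule for arm forces automatically.

Interaction tables
------------------
springs   harmonic distance springs: actin bonds, ACP arms, motor backbone
          bonds, motor transverse springs
axial     motor longitudinal springs: penalize the component of the arm
          vector along the bound actin segment axis (rest length 0)
angles    bending triplets: actin joints, ACP hinge, motor backbone joints
rep       candidate actin segment pairs for the overlap repulsion
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import minimum_image
from .params import Domain, ParameterSet, zeta_acp, zeta_actin, zeta_motor
from .state import SimulationState

KIND_ACTIN = 0
KIND_ACP = 1
KIND_BACKBONE = 2
KIND_MOTOR_TRANS = 3


@dataclasses.dataclass
class MechanicalSystem:
    P: np.ndarray
    zeta: np.ndarray
    noise_amp: np.ndarray
    springs_i: np.ndarray   # (ns, 4) a1, a2, b1, b2
    springs_f: np.ndarray   # (ns, 4) s1, s2, k, r0
    spring_kind: np.ndarray
    axial_i: np.ndarray     # (na, 3) a1, a2, anchor
    axial_f: np.ndarray     # (na, 2) s, k
    angles_i: np.ndarray    # (nA, 6) a1, a2, b1, b2, c1, c2
    angles_f: np.ndarray    # (nA, 5) sa, sb, sc, k, theta0
    actin_bonds: np.ndarray  # (m, 2) endpoint indices of actin segments
    bond_fil: np.ndarray     # (m,) filament ordinal
    bond_seg: np.ndarray     # (m,) segment index within filament
    rep_pairs: np.ndarray    # (nr, 4) p1, p2, q1, q2
    fil_offsets: list
    acp_offsets: dict
    motor_offsets: dict
    motor_arm_rows: dict     # (motor_uid, arm) -> (spring row, axial row)


def _site_attachment(offsets, fil_ordinals, site, params):
    fil, seg, idx = site
    base = offsets[fil_ordinals[id(fil)]]
    s = idx / params.sites_per_segment
    return base + seg, base + seg + 1, s


def build_system(state: SimulationState) -> MechanicalSystem:
    p = state.params
    pts, zetas = [], []
    fil_offsets, fil_ordinals = [], {}
    for k, f in enumerate(state.filaments):
        fil_ordinals[id(f)] = k
        fil_offsets.append(len(pts))
        pts.extend(f.points)
        zetas.extend([zeta_actin(p)] * f.points.shape[0])
    acp_offsets = {}
    for a in state.acps:
        acp_offsets[a.uid] = len(pts)
        pts.append(a.hinge)
        zetas.append(zeta_acp(p))
    motor_offsets = {}
    for m in state.motors:
        motor_offsets[m.uid] = len(pts)
        pts.extend(m.points)
        zetas.extend([zeta_motor(p)] * 4)

    springs_i, springs_f, kinds = [], [], []
    axial_i, axial_f = [], []
    angles_i, angles_f = [], []
    actin_bonds, bond_fil, bond_seg = [], [], []
    motor_arm_rows = {}

    for k, f in enumerate(state.filaments):
        base = fil_offsets[k]
        for s in range(f.n_segments):
            i, j = base + s, base + s + 1
            springs_i.append((i, i, j, j))
            springs_f.append((0.0, 0.0, p.ks_actin, p.r0_actin))
            kinds.append(KIND_ACTIN)
            actin_bonds.append((i, j))
            bond_fil.append(k)
            bond_seg.append(s)
        for s in range(f.n_segments - 1):
            a, b, c = base + s, base + s + 1, base + s + 2
            angles_i.append((a, a, b, b, c, c))
            angles_f.append((0.0, 0.0, 0.0, p.kb_actin, p.theta0_actin))

    for a in state.acps:
        h = acp_offsets[a.uid]
        atts = []
        for site in a.sites:
            if site is None:
                continue
            i, j, s = _site_attachment(fil_offsets, fil_ordinals, site, p)
            atts.append((i, j, s))
            springs_i.append((h, h, i, j))
            springs_f.append((0.0, s, p.ks_acp, p.r0_acp))
            kinds.append(KIND_ACP)
        if len(atts) == 2:
            (i1, j1, s1), (i2, j2, s2) = atts
            angles_i.append((i1, j1, h, h, i2, j2))
            angles_f.append((s1, 0.0, s2, p.kb_acp, p.theta0_acp))

    for m in state.motors:
        base = motor_offsets[m.uid]
        for s in range(3):
            springs_i.append((base + s, base + s, base + s + 1, base + s + 1))
            springs_f.append((0.0, 0.0, p.ks_motor_backbone, p.r0_motor_backbone))
            kinds.append(KIND_BACKBONE)
        for s in range(2):
            angles_i.append((base + s,) * 2 + (base + s + 1,) * 2 + (base + s + 2,) * 2)
            angles_f.append((0.0, 0.0, 0.0, p.kb_motor, p.theta0_motor))
        for arm, site in enumerate(m.arm_site):
            if site is None:
                continue
            anchor = base + m.arm_anchor[arm]
            i, j, s = _site_attachment(fil_offsets, fil_ordinals, site, p)
            motor_arm_rows[(m.uid, arm)] = (len(springs_i), len(axial_i))
            springs_i.append((anchor, anchor, i, j))
            springs_f.append((0.0, s, p.ks_motor_trans, p.r0_motor_trans))
            kinds.append(KIND_MOTOR_TRANS)
            axial_i.append((i, j, anchor))
            axial_f.append((s, p.ks_motor_long))

    P = np.array(pts, dtype=float).reshape(-1, 3)
    zeta = np.array(zetas, dtype=float)
    noise_amp = np.sqrt(2.0 * p.kBT * zeta / p.dt)

    def arr(x, shape, dt):
        return np.array(x, dtype=dt).reshape(-1, shape)

    return MechanicalSystem(
        P=P, zeta=zeta, noise_amp=noise_amp,
        springs_i=arr(springs_i, 4, np.int64), springs_f=arr(springs_f, 4, float),
        spring_kind=np.array(kinds, dtype=np.int8),
        axial_i=arr(axial_i, 3, np.int64), axial_f=arr(axial_f, 2, float),
        angles_i=arr(angles_i, 6, np.int64), angles_f=arr(angles_f, 5, float),
        actin_bonds=arr(actin_bonds, 2, np.int64),
        bond_fil=np.array(bond_fil, dtype=np.int64),
        bond_seg=np.array(bond_seg, dtype=np.int64),
        rep_pairs=np.zeros((0, 4), dtype=np.int64),
        fil_offsets=fil_offsets, acp_offsets=acp_offsets,
        motor_offsets=motor_offsets, motor_arm_rows=motor_arm_rows,
    )


def scatter(system: MechanicalSystem, state: SimulationState) -> None:
    """Write flat positions back into the object-level state."""
    for k, f in enumerate(state.filaments):
        base = system.fil_offsets[k]
        f.points[:] = system.P[base:base + f.points.shape[0]]
    for a in state.acps:
        a.hinge[:] = system.P[system.acp_offsets[a.uid]]
    for m in state.motors:
        base = system.motor_offsets[m.uid]
        m.points[:] = system.P[base:base + 4]


def rebuild_repulsion_pairs(system: MechanicalSystem, domain: Domain,
                            params: ParameterSet, margin: float = 30.0) -> None:
    """Broad-phase neighbor list for the actin-actin repulsion.

    Candidate pairs are actin segments whose midpoints (minimum image in y)
    lie within r0 + rc + margin; same-filament nearest neighbors are
    excluded since their spacing is maintained by the bonded terms.
    """
    bonds = system.actin_bonds
    m = bonds.shape[0]
    if m < 2:
        system.rep_pairs = np.zeros((0, 4), dtype=np.int64)
        return
    mid = 0.5 * (system.P[bonds[:, 0]] + system.P[bonds[:, 1]])
    d = mid[:, None, :] - mid[None, :, :]
    ly = domain.size_y
    d[..., 1] -= ly * np.round(d[..., 1] / ly)
    dist2 = np.einsum("ijk,ijk->ij", d, d)
    cutoff = params.r0_actin + params.rc_actin + margin
    close = dist2 < cutoff * cutoff
    iu, ju = np.triu_indices(m, k=1)
    mask = close[iu, ju]
    same_fil = system.bond_fil[iu] == system.bond_fil[ju]
    adjacent = same_fil & (np.abs(system.bond_seg[iu] - system.bond_seg[ju]) <= 1)
    mask &= ~adjacent
    ii, jj = iu[mask], ju[mask]
    system.rep_pairs = np.column_stack(
        [bonds[ii, 0], bonds[ii, 1], bonds[jj, 0], bonds[jj, 1]]
    ).astype(np.int64)


# ---------------------------------------------------------------------------
# NumPy reference force/energy evaluation (mirrors the compiled kernel)
# ---------------------------------------------------------------------------

def _att_pos(P, i, j, s, out=None):
    return (1.0 - s)[:, None] * P[i] + s[:, None] * P[j]


def _mi_y(d, ly):
    d[..., 1] -= ly * np.round(d[..., 1] / ly)
    return d


def compute_forces(system: MechanicalSystem, params: ParameterSet,
                   domain: Domain) -> np.ndarray:
    """Deterministic force on every flat point (reference implementation)."""
    from .geometry import closest_points_on_segments

    P = system.P
    ly = domain.size_y
    F = np.zeros_like(P)

    si, sf = system.springs_i, system.springs_f
    if si.shape[0]:
        pa = _att_pos(P, si[:, 0], si[:, 1], sf[:, 0])
        pb = _att_pos(P, si[:, 2], si[:, 3], sf[:, 1])
        d = _mi_y(pb - pa, ly)
        r = np.linalg.norm(d, axis=1)
        r = np.where(r < 1e-9, 1e-9, r)
        u = d / r[:, None]
        fmag = sf[:, 2] * (r - sf[:, 3])
        fv = fmag[:, None] * u
        w1, w2 = (1.0 - sf[:, 0]), sf[:, 0]
        np.add.at(F, si[:, 0], w1[:, None] * fv)
        np.add.at(F, si[:, 1], w2[:, None] * fv)
        w1, w2 = (1.0 - sf[:, 1]), sf[:, 1]
        np.add.at(F, si[:, 2], -w1[:, None] * fv)
        np.add.at(F, si[:, 3], -w2[:, None] * fv)

    ai, af = system.axial_i, system.axial_f
    if ai.shape[0]:
        t = _mi_y(P[ai[:, 1]] - P[ai[:, 0]], ly)
        t /= np.linalg.norm(t, axis=1)[:, None]
        att = _att_pos(P, ai[:, 0], ai[:, 1], af[:, 0])
        d = _mi_y(att - P[ai[:, 2]], ly)
        x = np.einsum("ij,ij->i", d, t)
        fv = -(af[:, 1] * x)[:, None] * t   # force on the attachment
        w1, w2 = (1.0 - af[:, 0]), af[:, 0]
        np.add.at(F, ai[:, 0], w1[:, None] * fv)
        np.add.at(F, ai[:, 1], w2[:, None] * fv)
        np.add.at(F, ai[:, 2], -fv)

    gi, gf = system.angles_i, system.angles_f
    if gi.shape[0]:
        pa = _att_pos(P, gi[:, 0], gi[:, 1], gf[:, 0])
        pb = _att_pos(P, gi[:, 2], gi[:, 3], gf[:, 1])
        pc = _att_pos(P, gi[:, 4], gi[:, 5], gf[:, 2])
        u = _mi_y(pb - pa, ly)
        v = _mi_y(pc - pb, ly)
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        t1 = u / nu[:, None]
        t2 = v / nv[:, None]
        c = np.clip(np.einsum("ij,ij->i", t1, t2), -1.0, 1.0)
        theta = np.arccos(c)
        sin = np.maximum(np.sqrt(np.clip(1.0 - c * c, 0.0, None)), 1e-8)
        coef = gf[:, 3] * (theta - gf[:, 4]) / sin
        dcdu = (t2 - c[:, None] * t1) / nu[:, None]
        dcdv = (t1 - c[:, None] * t2) / nv[:, None]
        fa = -coef[:, None] * dcdu
        fc = coef[:, None] * dcdv
        fb = -fa - fc
        for col, (i1, i2, fr) in enumerate(((0, 1, 0), (2, 3, 1), (4, 5, 2))):
            fv = (fa, fb, fc)[col]
            w = gf[:, fr]
            np.add.at(F, gi[:, i1], (1.0 - w)[:, None] * fv)
            np.add.at(F, gi[:, i2], w[:, None] * fv)

    rp = system.rep_pairs
    for p1, p2, q1, q2 in rp:
        seg1 = np.array([P[p1], P[p2]])
        q = np.array([P[q1], P[q2]])
        mid_dy = 0.5 * (q[0, 1] + q[1, 1]) - 0.5 * (seg1[0, 1] + seg1[1, 1])
        q[:, 1] -= ly * np.round(mid_dy / ly)
        r12, s, t, cp, cq = closest_points_on_segments(seg1[0], seg1[1], q[0], q[1])
        if r12 >= params.rc_actin:
            continue
        axis = (cq - cp) / r12 if r12 > 1e-9 else np.array([1.0, 0.0, 0.0])
        fmag = params.kr_repulsion * (params.rc_actin - r12)
        f2 = fmag * axis
        F[p1] += -(1.0 - s) * f2
        F[p2] += -s * f2
        F[q1] += (1.0 - t) * f2
        F[q2] += t * f2

    # walls (x and z)
    kw = params.k_wall
    for axis, size in ((0, domain.size_x), (2, domain.size_z)):
        x = P[:, axis]
        F[:, axis] += np.where(x < 0.0, -kw * x,
                               np.where(x > size, kw * (size - x), 0.0))
    return F


def total_energy(system: MechanicalSystem, params: ParameterSet,
                 domain: Domain) -> float:
    """Total potential energy (springs + axial + bending + repulsion + walls)."""
    from .geometry import closest_points_on_segments

    P = system.P
    ly = domain.size_y
    e = 0.0
    si, sf = system.springs_i, system.springs_f
    if si.shape[0]:
        pa = _att_pos(P, si[:, 0], si[:, 1], sf[:, 0])
        pb = _att_pos(P, si[:, 2], si[:, 3], sf[:, 1])
        r = np.linalg.norm(_mi_y(pb - pa, ly), axis=1)
        e += float(np.sum(0.5 * sf[:, 2] * (r - sf[:, 3]) ** 2))
    ai, af = system.axial_i, system.axial_f
    if ai.shape[0]:
        t = _mi_y(P[ai[:, 1]] - P[ai[:, 0]], ly)
        t /= np.linalg.norm(t, axis=1)[:, None]
        att = _att_pos(P, ai[:, 0], ai[:, 1], af[:, 0])
        x = np.einsum("ij,ij->i", _mi_y(att - P[ai[:, 2]], ly), t)
        e += float(np.sum(0.5 * af[:, 1] * x ** 2))
    gi, gf = system.angles_i, system.angles_f
    if gi.shape[0]:
        pa = _att_pos(P, gi[:, 0], gi[:, 1], gf[:, 0])
        pb = _att_pos(P, gi[:, 2], gi[:, 3], gf[:, 1])
        pc = _att_pos(P, gi[:, 4], gi[:, 5], gf[:, 2])
        u = _mi_y(pb - pa, ly)
        v = _mi_y(pc - pb, ly)
        c = np.clip(np.einsum("ij,ij->i", u, v)
                    / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)),
                    -1.0, 1.0)
        e += float(np.sum(0.5 * gf[:, 3] * (np.arccos(c) - gf[:, 4]) ** 2))
    for p1, p2, q1, q2 in system.rep_pairs:
        seg1 = np.array([P[p1], P[p2]])
        q = np.array([P[q1], P[q2]])
        mid_dy = 0.5 * (q[0, 1] + q[1, 1]) - 0.5 * (seg1[0, 1] + seg1[1, 1])
        q[:, 1] -= ly * np.round(mid_dy / ly)
        r12 = closest_points_on_segments(seg1[0], seg1[1], q[0], q[1])[0]
        if r12 < params.rc_actin:
            e += 0.5 * params.kr_repulsion * (r12 - params.rc_actin) ** 2
    for axis, size in ((0, domain.size_x), (2, domain.size_z)):
        x = P[:, axis]
        e += 0.5 * params.k_wall * float(
            np.sum(np.clip(-x, 0, None) ** 2 + np.clip(x - size, 0, None) ** 2))
    return e
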