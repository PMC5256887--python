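"""Deterministic forces: extensional, bending, repulsive, wall, lever rules.

All potentials are harmonic:

    U_s = 1/2 ks (r - r0)^2                  (extension of a segment)
    U_b = 1/2 kb (theta - theta0)^2          (angle between adjacent segments)
    U_r = 1/2 kr (r12 - rc)^2  for r12 < rc  (actin-actin overlap)

Forces returned by these functions are exact negative gradients of the
potentials (verified against central finite differences in the test suite);
the angle force uses the theta/sin(theta) regularized form, smooth through
theta = 0 and clamped near theta = pi.
"""
from __future__ import annotations

import numpy as np

from .geometry import minimum_image, segment_segment_distance
from .params import Domain, drag_coefficient  # noqa: F401  (re-exported)

_EPS_R = 1e-9
_EPS_SIN = 1e-8


def extensional_forces(p0, p1, r0: float, ks: float, domain: Domain | None = None):
    """Force pair (on p0, on p1) of a harmonic bond; contractile when stretched."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = minimum_image(p0, p1, domain) if domain is not None else p1 - p0
    r = float(np.linalg.norm(d))
    if r < _EPS_R:
        # direction undefined at exact coincidence; perturb along a fixed axis
        d = np.array([_EPS_R, 0.0, 0.0])
        r = _EPS_R
    u = d / r
    fmag = ks * (r - r0)       # >0 stretched: p0 pulled toward p1
    return fmag * u, -fmag * u


def extensional_energy(p0, p1, r0: float, ks: float, domain: Domain | None = None) -> float:
    d = minimum_image(p0, p1, domain) if domain is not None else np.asarray(p1, float) - np.asarray(p0, float)
    return 0.5 * ks * (float(np.linalg.norm(d)) - r0) ** 2


def _angle_geometry(pa, pb, pc, domain):
    if domain is not None:
        u = minimum_image(pa, pb, domain)
        v = minimum_image(pb, pc, domain)
    else:
        u = np.asarray(pb, float) - np.asarray(pa, float)
        v = np.asarray(pc, float) - np.asarray(pb, float)
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    t1 = u / nu
    t2 = v / nv
    c = float(np.clip(t1 @ t2, -1.0, 1.0))
    return t1, t2, nu, nv, c


def bending_forces(pa, pb, pc, theta0: float, kb: float, domain: Domain | None = None):
    """Forces on an endpoint triplet from U_b = 1/2 kb (theta - theta0)^2.

    theta is the deflection between consecutive segment directions
    (theta = 0 for a straight continuation).  Exact -grad U; the net force
    and net torque of the triplet vanish.
    """
    t1, t2, nu, nv, c = _angle_geometry(pa, pb, pc, domain)
    theta = float(np.arccos(c))
    sin = max(np.sqrt(max(0.0, 1.0 - c * c)), _EPS_SIN)
    coef = kb * (theta - theta0) / sin
    dcdu = (t2 - c * t1) / nu
    dcdv = (t1 - c * t2) / nv
    # F = -grad U = kb (theta - theta0) / sin(theta) * grad(cos theta)
    fa = -coef * dcdu
    fc = coef * dcdv
    fb = -fa - fc
    return fa, fb, fc


def bending_energy(pa, pb, pc, theta0: float, kb: float, domain: Domain | None = None) -> float:
    *_, c = _angle_geometry(pa, pb, pc, domain)
    return 0.5 * kb * (float(np.arccos(c)) - theta0) ** 2


def redistribute_arm_force(s: float, force):
    """Lever rule: split a force applied at arc fraction s onto segment ends.

    Returns (force on pointed-side endpoint, force on barbed-side endpoint);
    the two sum to the input force.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("arc fraction must lie in [0, 1]")
    force = np.asarray(force, dtype=float)
    return (1.0 - s) * force, s * force


def repulsive_forces(seg1, seg2, kr: float, rc: float, domain: Domain | None = None):
    """Endpoint forces of the actin-actin overlap potential.

    Zero if the minimum segment distance r12 >= rc; otherwise the pair force
    kr*(rc - r12) acts along the closest-point axis and is lever-distributed
    to the four endpoints.  Returns (f_p1, f_p2, f_q1, f_q2, r12).
    """
    r12, s, t, cp, cq = segment_segment_distance(seg1, seg2, domain)
    zeros = np.zeros(3)
    if r12 >= rc:
        return zeros, zeros, zeros, zeros, r12
    if r12 < _EPS_R:
        axis = np.array([1.0, 0.0, 0.0])  # arbitrary fixed push-apart axis
    else:
        axis = (cq - cp) / r12
    fmag = kr * (rc - r12)
    f_on_2 = fmag * axis       # pushes segment 2 away from segment 1
    f_on_1 = -f_on_2
    f_p1, f_p2 = redistribute_arm_force(s, f_on_1)
    f_q1, f_q2 = redistribute_arm_force(t, f_on_2)
    return f_p1, f_p2, f_q1, f_q2, r12


def repulsive_energy(seg1, seg2, kr: float, rc: float, domain: Domain | None = None) -> float:
    r12 = segment_segment_distance(seg1, seg2, domain)[0]
    return 0.5 * kr * (r12 - rc) ** 2 if r12 < rc else 0.0


def wall_forces(pos, domain: Domain, k_wall: float):
    """Harmonic restoring force for points beyond the x or z boundaries.

    Zero inside the domain; the periodic y direction has no walls.
    """
    pos = np.asarray(pos, dtype=float)
    f = np.zeros_like(pos)
    for axis, size in ((0, domain.size_x), (2, domain.size_z)):
        x = pos[..., axis]
        f[..., axis] = np.where(x < 0.0, -k_wall * x,
                                np.where(x > size, k_wall * (size - x), 0.0))
    return f


def wall_energy(pos, domain: Domain, k_wall: float) -> float:
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    e = 0.0
    for axis, size in ((0, domain.size_x), (2, domain.size_z)):
        x = pos[..., axis]
        over = np.clip(x - size, 0.0, None)
        under = np.clip(-x, 0.0, None)
        e += 0.5 * k_wall * float(np.sum(over ** 2 + under ** 2))
    return e
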