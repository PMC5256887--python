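"""Numba-compiled inner loop of the overdamped Langevin integrator.

The kernel advances a flattened mechanical system by N explicit Euler steps
with fixed interaction topology; binding/unbinding/walking/turnover events
are handled outside between kernel calls.  The deterministic force math is
the exact counterpart of :func:`actomyo.flatten.compute_forces` (asserted by
a consistency test).
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False, fastmath=False)
def _closest_params(p1x, p1y, p1z, p2x, p2y, p2z,
                    q1x, q1y, q1z, q2x, q2y, q2z):
    """Closest-point parameters (s, t) between two finite segments."""
    eps = 1e-12
    d1x, d1y, d1z = p2x - p1x, p2y - p1y, p2z - p1z
    d2x, d2y, d2z = q2x - q1x, q2y - q1y, q2z - q1z
    rx, ry, rz = p1x - q1x, p1y - q1y, p1z - q1z
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    f = d2x * rx + d2y * ry + d2z * rz
    if a <= eps and e <= eps:
        return 0.0, 0.0
    if a <= eps:
        t = f / e
        return 0.0, min(1.0, max(0.0, t))
    c = d1x * rx + d1y * ry + d1z * rz
    if e <= eps:
        s = -c / a
        return min(1.0, max(0.0, s)), 0.0
    b = d1x * d2x + d1y * d2y + d1z * d2z
    denom = a * e - b * b
    if denom > eps:
        s = (b * f - c * e) / denom
        s = min(1.0, max(0.0, s))
    else:
        s = 0.0
    t = (b * s + f) / e
    if t < 0.0:
        t = 0.0
        s = min(1.0, max(0.0, -c / a))
    elif t > 1.0:
        t = 1.0
        s = min(1.0, max(0.0, (b - c) / a))
    return s, t


@njit(cache=False, fastmath=False)
def run_kernel(P, zeta, noise_amp, noise, nsteps, dt, ly,
               springs_i, springs_f, axial_i, axial_f,
               angles_i, angles_f, rep_pairs, k_rep, rc,
               k_wall, lx, lz, use_noise):
    """Advance positions in place; returns the largest single-step displacement.

    ``noise`` holds pre-drawn standard normal deviates of shape
    (nsteps, n, 3) when ``use_noise`` is set (generated outside so the whole
    run shares one seeded stream).
    """
    n = P.shape[0]
    ns = springs_i.shape[0]
    na = axial_i.shape[0]
    nA = angles_i.shape[0]
    nr = rep_pairs.shape[0]
    F = np.zeros((n, 3))
    max_disp = 0.0

    for step in range(nsteps):
        for i in range(n):
            F[i, 0] = 0.0
            F[i, 1] = 0.0
            F[i, 2] = 0.0

        # distance springs (attachment endpoints, lever redistribution)
        for k in range(ns):
            a1, a2, b1, b2 = springs_i[k, 0], springs_i[k, 1], springs_i[k, 2], springs_i[k, 3]
            s1, s2, ks, r0 = springs_f[k, 0], springs_f[k, 1], springs_f[k, 2], springs_f[k, 3]
            dx = (1.0 - s2) * P[b1, 0] + s2 * P[b2, 0] - ((1.0 - s1) * P[a1, 0] + s1 * P[a2, 0])
            dy = (1.0 - s2) * P[b1, 1] + s2 * P[b2, 1] - ((1.0 - s1) * P[a1, 1] + s1 * P[a2, 1])
            dz = (1.0 - s2) * P[b1, 2] + s2 * P[b2, 2] - ((1.0 - s1) * P[a1, 2] + s1 * P[a2, 2])
            dy -= ly * np.rint(dy / ly)
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < 1e-9:
                r = 1e-9
                dx = 1e-9
                dy = 0.0
                dz = 0.0
            g = ks * (r - r0) / r
            fx, fy, fz = g * dx, g * dy, g * dz
            F[a1, 0] += (1.0 - s1) * fx
            F[a1, 1] += (1.0 - s1) * fy
            F[a1, 2] += (1.0 - s1) * fz
            F[a2, 0] += s1 * fx
            F[a2, 1] += s1 * fy
            F[a2, 2] += s1 * fz
            F[b1, 0] -= (1.0 - s2) * fx
            F[b1, 1] -= (1.0 - s2) * fy
            F[b1, 2] -= (1.0 - s2) * fz
            F[b2, 0] -= s2 * fx
            F[b2, 1] -= s2 * fy
            F[b2, 2] -= s2 * fz

        # motor longitudinal springs (frozen-axis projection)
        for k in range(na):
            i1, i2, anc = axial_i[k, 0], axial_i[k, 1], axial_i[k, 2]
            s, ks = axial_f[k, 0], axial_f[k, 1]
            tx = P[i2, 0] - P[i1, 0]
            ty = P[i2, 1] - P[i1, 1]
            tz = P[i2, 2] - P[i1, 2]
            ty -= ly * np.rint(ty / ly)
            tn = np.sqrt(tx * tx + ty * ty + tz * tz)
            if tn < 1e-9:
                continue
            tx, ty, tz = tx / tn, ty / tn, tz / tn
            ax = (1.0 - s) * P[i1, 0] + s * P[i2, 0] - P[anc, 0]
            ay = (1.0 - s) * P[i1, 1] + s * P[i2, 1] - P[anc, 1]
            az = (1.0 - s) * P[i1, 2] + s * P[i2, 2] - P[anc, 2]
            ay -= ly * np.rint(ay / ly)
            x = ax * tx + ay * ty + az * tz
            fx, fy, fz = -ks * x * tx, -ks * x * ty, -ks * x * tz
            F[i1, 0] += (1.0 - s) * fx
            F[i1, 1] += (1.0 - s) * fy
            F[i1, 2] += (1.0 - s) * fz
            F[i2, 0] += s * fx
            F[i2, 1] += s * fy
            F[i2, 2] += s * fz
            F[anc, 0] -= fx
            F[anc, 1] -= fy
            F[anc, 2] -= fz

        # bending triplets
        for k in range(nA):
            a1, a2 = angles_i[k, 0], angles_i[k, 1]
            b1, b2 = angles_i[k, 2], angles_i[k, 3]
            c1, c2 = angles_i[k, 4], angles_i[k, 5]
            sa, sb, sc = angles_f[k, 0], angles_f[k, 1], angles_f[k, 2]
            kb, th0 = angles_f[k, 3], angles_f[k, 4]
            pax = (1.0 - sa) * P[a1, 0] + sa * P[a2, 0]
            pay = (1.0 - sa) * P[a1, 1] + sa * P[a2, 1]
            paz = (1.0 - sa) * P[a1, 2] + sa * P[a2, 2]
            pbx = (1.0 - sb) * P[b1, 0] + sb * P[b2, 0]
            pby = (1.0 - sb) * P[b1, 1] + sb * P[b2, 1]
            pbz = (1.0 - sb) * P[b1, 2] + sb * P[b2, 2]
            pcx = (1.0 - sc) * P[c1, 0] + sc * P[c2, 0]
            pcy = (1.0 - sc) * P[c1, 1] + sc * P[c2, 1]
            pcz = (1.0 - sc) * P[c1, 2] + sc * P[c2, 2]
            ux, uy, uz = pbx - pax, pby - pay, pbz - paz
            vx, vy, vz = pcx - pbx, pcy - pby, pcz - pbz
            uy -= ly * np.rint(uy / ly)
            vy -= ly * np.rint(vy / ly)
            nu = np.sqrt(ux * ux + uy * uy + uz * uz)
            nv = np.sqrt(vx * vx + vy * vy + vz * vz)
            if nu < 1e-9 or nv < 1e-9:
                continue
            t1x, t1y, t1z = ux / nu, uy / nu, uz / nu
            t2x, t2y, t2z = vx / nv, vy / nv, vz / nv
            c = t1x * t2x + t1y * t2y + t1z * t2z
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            theta = np.arccos(c)
            sin = np.sqrt(max(0.0, 1.0 - c * c))
            if sin < 1e-8:
                sin = 1e-8
            coef = kb * (theta - th0) / sin
            dux = (t2x - c * t1x) / nu
            duy = (t2y - c * t1y) / nu
            duz = (t2z - c * t1z) / nu
            dvx = (t1x - c * t2x) / nv
            dvy = (t1y - c * t2y) / nv
            dvz = (t1z - c * t2z) / nv
            fax, fay, faz = -coef * dux, -coef * duy, -coef * duz
            fcx, fcy, fcz = coef * dvx, coef * dvy, coef * dvz
            fbx, fby, fbz = -fax - fcx, -fay - fcy, -faz - fcz
            F[a1, 0] += (1.0 - sa) * fax
            F[a1, 1] += (1.0 - sa) * fay
            F[a1, 2] += (1.0 - sa) * faz
            F[a2, 0] += sa * fax
            F[a2, 1] += sa * fay
            F[a2, 2] += sa * faz
            F[b1, 0] += (1.0 - sb) * fbx
            F[b1, 1] += (1.0 - sb) * fby
            F[b1, 2] += (1.0 - sb) * fbz
            F[b2, 0] += sb * fbx
            F[b2, 1] += sb * fby
            F[b2, 2] += sb * fbz
            F[c1, 0] += (1.0 - sc) * fcx
            F[c1, 1] += (1.0 - sc) * fcy
            F[c1, 2] += (1.0 - sc) * fcz
            F[c2, 0] += sc * fcx
            F[c2, 1] += sc * fcy
            F[c2, 2] += sc * fcz

        # actin-actin repulsion on candidate pairs
        for k in range(nr):
            p1, p2, q1, q2 = rep_pairs[k, 0], rep_pairs[k, 1], rep_pairs[k, 2], rep_pairs[k, 3]
            mid_dy = 0.5 * (P[q1, 1] + P[q2, 1]) - 0.5 * (P[p1, 1] + P[p2, 1])
            shift = -ly * np.rint(mid_dy / ly)
            # broad-phase early exit: midpoints too far for any overlap
            mdx = 0.5 * (P[q1, 0] + P[q2, 0]) - 0.5 * (P[p1, 0] + P[p2, 0])
            mdy = mid_dy + shift
            mdz = 0.5 * (P[q1, 2] + P[q2, 2]) - 0.5 * (P[p1, 2] + P[p2, 2])
            far = rc + 160.0
            if mdx * mdx + mdy * mdy + mdz * mdz > far * far:
                continue
            q1y = P[q1, 1] + shift
            q2y = P[q2, 1] + shift
            s, t = _closest_params(P[p1, 0], P[p1, 1], P[p1, 2],
                                   P[p2, 0], P[p2, 1], P[p2, 2],
                                   P[q1, 0], q1y, P[q1, 2],
                                   P[q2, 0], q2y, P[q2, 2])
            cpx = (1.0 - s) * P[p1, 0] + s * P[p2, 0]
            cpy = (1.0 - s) * P[p1, 1] + s * P[p2, 1]
            cpz = (1.0 - s) * P[p1, 2] + s * P[p2, 2]
            cqx = (1.0 - t) * P[q1, 0] + t * P[q2, 0]
            cqy = (1.0 - t) * q1y + t * q2y
            cqz = (1.0 - t) * P[q1, 2] + t * P[q2, 2]
            dx, dy, dz = cqx - cpx, cqy - cpy, cqz - cpz
            r12 = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r12 >= rc:
                continue
            if r12 > 1e-9:
                axx, axy, axz = dx / r12, dy / r12, dz / r12
            else:
                axx, axy, axz = 1.0, 0.0, 0.0
            fm = k_rep * (rc - r12)
            fx, fy, fz = fm * axx, fm * axy, fm * axz
            F[p1, 0] -= (1.0 - s) * fx
            F[p1, 1] -= (1.0 - s) * fy
            F[p1, 2] -= (1.0 - s) * fz
            F[p2, 0] -= s * fx
            F[p2, 1] -= s * fy
            F[p2, 2] -= s * fz
            F[q1, 0] += (1.0 - t) * fx
            F[q1, 1] += (1.0 - t) * fy
            F[q1, 2] += (1.0 - t) * fz
            F[q2, 0] += t * fx
            F[q2, 1] += t * fy
            F[q2, 2] += t * fz

        # walls in x and z, thermal noise, Euler update, y wrapping
        for i in range(n):
            x = P[i, 0]
            if x < 0.0:
                F[i, 0] += -k_wall * x
            elif x > lx:
                F[i, 0] += k_wall * (lx - x)
            z = P[i, 2]
            if z < 0.0:
                F[i, 2] += -k_wall * z
            elif z > lz:
                F[i, 2] += k_wall * (lz - z)
            scale = dt / zeta[i]
            if use_noise:
                fx = F[i, 0] + noise_amp[i] * noise[step, i, 0]
                fy = F[i, 1] + noise_amp[i] * noise[step, i, 1]
                fz = F[i, 2] + noise_amp[i] * noise[step, i, 2]
            else:
                fx, fy, fz = F[i, 0], F[i, 1], F[i, 2]
            ddx = fx * scale
            ddy = fy * scale
            ddz = fz * scale
            disp = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
            if disp > max_disp:
                max_disp = disp
            P[i, 0] += ddx
            P[i, 1] = (P[i, 1] + ddy) % ly
            P[i, 2] += ddz
    return max_disp
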