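"""Periodic-boundary geometry utilities.

Only the y axis is periodic; x and z are bounded by repulsive walls, so
minimum-image corrections apply to the y component alone.
"""
from __future__ import annotations

import numpy as np

from .params import Domain


def minimum_image(p: np.ndarray, q: np.ndarray, domain: Domain) -> np.ndarray:
    """Displacement q - p with the y component mapped to (-Ly/2, Ly/2].

    Works on single points or broadcastable stacks of points.
    """
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    if domain.periodic_y:
        ly = domain.size_y
        d = d.copy()
        # map into (-Ly/2, Ly/2]; note floor((x/Ly)+0.5) keeps +Ly/2 itself
        d[..., 1] -= ly * np.floor(d[..., 1] / ly + 0.5)
        half = d[..., 1] == -ly / 2.0
        if np.any(half):
            d[..., 1] = np.where(half, ly / 2.0, d[..., 1])
    return d


def wrap_y(points: np.ndarray, domain: Domain) -> np.ndarray:
    return domain.wrap_y(points)


def unwrap_chain(points: np.ndarray, domain: Domain) -> np.ndarray:
    """Unwrap an ordered chain of points into continuous coordinates.

    Starts from the first point and accumulates minimum-image steps, so
    end-to-end and contour lengths are well defined for filaments crossing
    the periodic y boundary.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2 or not domain.periodic_y:
        return pts.copy()
    steps = minimum_image(pts[:-1], pts[1:], domain)
    out = np.empty_like(pts)
    out[0] = pts[0]
    out[1:] = pts[0] + np.cumsum(steps, axis=0)
    return out


def closest_points_on_segments(p1, p2, q1, q2, eps: float = 1e-12):
    """Closest points between finite segments [p1,p2] and [q1,q2].

    Returns (distance, s, t, cp, cq) where s, t in [0, 1] parametrize the
    closest points cp = p1 + s*(p2-p1), cq = q1 + t*(q2-q1).  Degenerate
    zero-length segments are treated as points.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    d1 = p2 - p1
    d2 = q2 - q1
    r = p1 - q1
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r

    if a <= eps and e <= eps:
        s = t = 0.0
    elif a <= eps:
        s = 0.0
        t = float(np.clip(f / e, 0.0, 1.0))
    else:
        c = d1 @ r
        if e <= eps:
            t = 0.0
            s = float(np.clip(-c / a, 0.0, 1.0))
        else:
            b = d1 @ d2
            denom = a * e - b * b
            s = float(np.clip((b * f - c * e) / denom, 0.0, 1.0)) if denom > eps else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = float(np.clip(-c / a, 0.0, 1.0))
            elif t > 1.0:
                t = 1.0
                s = float(np.clip((b - c) / a, 0.0, 1.0))
    cp = p1 + s * d1
    cq = q1 + t * d2
    return float(np.linalg.norm(cq - cp)), s, t, cp, cq


def segment_segment_distance(seg1, seg2, domain: Domain | None = None):
    """Minimum distance between two finite segments under minimum image in y.

    ``seg1``/``seg2`` are (2, 3) arrays of endpoints.  Returns
    (distance, s, t, cp, cq); cq is expressed in the y image closest to seg1.
    """
    p1, p2 = np.asarray(seg1, dtype=float)
    q1, q2 = np.asarray(seg2, dtype=float)
    if domain is None or not domain.periodic_y:
        return closest_points_on_segments(p1, p2, q1, q2)
    ly = domain.size_y
    best = None
    mid_dy = 0.5 * (q1[1] + q2[1]) - 0.5 * (p1[1] + p2[1])
    base_shift = -ly * np.round(mid_dy / ly)
    for extra in (-ly, 0.0, ly):
        shift = np.array([0.0, base_shift + extra, 0.0])
        res = closest_points_on_segments(p1, p2, q1 + shift, q2 + shift)
        if best is None or res[0] < best[0]:
            best = res
    return best
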