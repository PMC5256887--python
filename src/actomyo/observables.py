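"""Measurements on actomyosin states and trajectories.

Bundle tension sums the axial (y) component of the extensional forces of
every element crossing each of 10 cross-sections normal to y and averages
over the sections; stretched spanning elements count positive, compressed
ones negative.  Sustainability compares late-run tension to the peak.
Network compaction is tracked by the standard deviation of actin x
positions (sigma_x); the compaction time is the first time the smoothed
rate of change of sigma_x rises above 1% of its early-run average.
Buckling is flagged per filament when end-to-end/contour falls below 0.6.
"""
from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .flatten import build_system
from .geometry import minimum_image
from .params import Domain
from .state import SimulationState

BUCKLING_THRESHOLD = 0.6


@dataclasses.dataclass
class TensionSeries:
    time: np.ndarray
    tension: np.ndarray

    @property
    def peak(self) -> float:
        return float(np.max(self.tension))

    @property
    def peak_time(self) -> float:
        return float(self.time[int(np.argmax(self.tension))])


@dataclasses.dataclass
class CompactionResult:
    compaction_time: Optional[float]
    sigma_xc: Optional[float]
    time: np.ndarray
    sigma_x: np.ndarray

    @property
    def reached(self) -> bool:
        return self.compaction_time is not None


@dataclasses.dataclass
class OrientationStats:
    azimuths: np.ndarray          # per filament, radians in [0, 2pi)
    histogram: np.ndarray
    bin_edges: np.ndarray
    antiparallel_fraction: float
    n_pairs: int


# ---------------------------------------------------------------------------
# tension
# ---------------------------------------------------------------------------

def _tension_elements(state: SimulationState, system=None):
    """(y1, dy, axial force component) of every force-carrying element.

    Returns the first endpoint y, the minimum-image y extent, and the signed
    tension times |cos| of the element axis with y (positive = contractile).
    """
    if system is None:
        system = build_system(state)
    p = state.params
    ly = state.domain.size_y
    P = system.P
    si, sf = system.springs_i, system.springs_f
    y1s, dys, vals = [], [], []
    if si.shape[0]:
        pa = (1.0 - sf[:, 0])[:, None] * P[si[:, 0]] + sf[:, 0][:, None] * P[si[:, 1]]
        pb = (1.0 - sf[:, 1])[:, None] * P[si[:, 2]] + sf[:, 1][:, None] * P[si[:, 3]]
        d = pb - pa
        d[:, 1] -= ly * np.round(d[:, 1] / ly)
        r = np.linalg.norm(d, axis=1)
        good = r > 1e-9
        tension = sf[:, 2] * (r - sf[:, 3])
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_y = np.abs(d[:, 1]) / r
        y1s.append(pa[good, 1])
        dys.append(d[good, 1])
        vals.append((tension * cos_y)[good])
    ai, af = system.axial_i, system.axial_f
    if ai.shape[0]:
        t = P[ai[:, 1]] - P[ai[:, 0]]
        t[:, 1] -= ly * np.round(t[:, 1] / ly)
        t /= np.linalg.norm(t, axis=1)[:, None]
        att = (1.0 - af[:, 0])[:, None] * P[ai[:, 0]] + af[:, 0][:, None] * P[ai[:, 1]]
        d = att - P[ai[:, 2]]
        d[:, 1] -= ly * np.round(d[:, 1] / ly)
        x = np.einsum("ij,ij->i", d, t)   # >0: attachment leads toward barbed
        y1s.append(P[ai[:, 2], 1])
        dys.append(d[:, 1])
        vals.append(af[:, 1] * x * np.abs(t[:, 1]))
    if not y1s:
        return (np.zeros(0),) * 3
    return np.concatenate(y1s), np.concatenate(dys), np.concatenate(vals)


def bundle_tension(state: SimulationState, n_sections: int = 10,
                   system=None) -> float:
    """Mean tension (pN) across regularly spaced cross-sections normal to y."""
    y1, dy, val = _tension_elements(state, system)
    if y1.size == 0:
        return 0.0
    ly = state.domain.size_y
    total = 0.0
    for k in range(n_sections):
        yc = (k + 0.5) * ly / n_sections
        u = (y1 - yc) % ly
        u = np.where(u > ly / 2, u - ly, u)   # signed offset of endpoint 1
        crossing = ((u < 0) & (u + dy > 0)) | ((u > 0) & (u + dy < 0))
        total += float(np.sum(val[crossing]))
    return total / n_sections


def sustainability(time, tension) -> Optional[float]:
    """Late-run tension retention in [0, 1]: mean over the final quarter of
    the run divided by the peak; None when the peak is not positive."""
    time = np.asarray(time, dtype=float)
    tension = np.asarray(tension, dtype=float)
    if tension.size == 0:
        return None
    peak = float(np.max(tension))
    if peak <= 0:
        return None
    t0 = time[0] + 0.75 * (time[-1] - time[0])
    tail = tension[time >= t0]
    return float(np.clip(np.mean(tail) / peak, 0.0, 1.0))


def microscopic_forces(state: SimulationState):
    """Signed per-arm forces f_ACP and f_M (pN), projected on the barbed-end
    direction of the bound filament.

    f_ACP is the extensional force of an ACP arm; f_M is the longitudinal
    spring force of a motor arm divided by the number of heads per arm.
    Positive values point toward the barbed end.
    """
    p = state.params
    domain = state.domain
    f_acp = []
    for acp in state.acps:
        for site in acp.sites:
            if site is None:
                continue
            fil, seg, idx = site
            att = fil.site_position(seg, idx, p)
            d = minimum_image(acp.hinge, att, domain)
            r = float(np.linalg.norm(d))
            if r < 1e-12:
                continue
            u = fil.orientation(domain)
            f_vec = p.ks_acp * (r - p.r0_acp) * (d / r)
            f_acp.append(float(f_vec @ u))
    f_m = []
    for m in state.motors:
        for arm, site in enumerate(m.arm_site):
            if site is None:
                continue
            fil, seg, idx = site
            t_hat = fil.segment_unit(seg, domain)
            d = minimum_image(m.anchor_point(arm), fil.site_position(seg, idx, p), domain)
            f_m.append(p.ks_motor_long * float(d @ t_hat) / p.n_heads)
    return np.array(f_acp), np.array(f_m)


# ---------------------------------------------------------------------------
# compaction
# ---------------------------------------------------------------------------

def sigma_x(state: SimulationState) -> float:
    """Population standard deviation of actin endpoint x positions (nm)."""
    pts = state.actin_points()
    if pts.shape[0] < 2:
        raise ValueError("sigma_x needs at least two actin endpoints")
    return float(np.std(pts[:, 0]))


def compaction_metrics(time, sigma, baseline_window: float = 5.0,
                       smooth_window: float = 1.0) -> CompactionResult:
    """Compaction time and sigma_x^c from a sigma_x(t) series.

    The rate dsigma_x/dt is smoothed with a moving linear fit of width
    ``smooth_window``; the baseline is its mean over the first
    ``baseline_window`` seconds (negative while the network compacts).  The
    compaction time is the first t beyond the baseline window where the rate
    exceeds 0.01 * baseline; if the baseline is not negative the criterion is
    flagged as not reached.
    """
    time = np.asarray(time, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if time.size < 3 or time[-1] - time[0] < baseline_window:
        raise ValueError("series must cover the baseline window")
    dt = np.median(np.diff(time))
    half = max(1, int(round(0.5 * smooth_window / dt)))
    rate = np.full_like(sigma, np.nan)
    for i in range(len(time)):
        lo, hi = max(0, i - half), min(len(time), i + half + 1)
        if hi - lo >= 2:
            rate[i] = np.polyfit(time[lo:hi], sigma[lo:hi], 1)[0]
    base_mask = time <= time[0] + baseline_window
    baseline = float(np.nanmean(rate[base_mask]))
    if not baseline < -1e-12:
        return CompactionResult(None, None, time, sigma)
    threshold = 0.01 * baseline
    after = np.nonzero((time > time[0] + baseline_window) & (rate > threshold))[0]
    if after.size == 0:
        return CompactionResult(None, None, time, sigma)
    k = int(after[0])
    return CompactionResult(float(time[k]), float(sigma[k]), time, sigma)


# ---------------------------------------------------------------------------
# buckling
# ---------------------------------------------------------------------------

def shape_ratios(state: SimulationState) -> dict:
    """End-to-end over contour length per filament uid (1 = straight)."""
    return {f.uid: f.shape_ratio(state.domain) for f in state.filaments}


def buckling_census(ratio_frames, threshold: float = BUCKLING_THRESHOLD):
    """Census over a trajectory of per-filament shape-ratio dicts.

    Returns (buckled_uids, n_ever_buckled, per_frame_counts): a filament
    counts once if its ratio drops strictly below the threshold in any
    frame; per-frame counts list how many filaments are buckled in each
    frame.
    """
    ever = set()
    per_frame = []
    for frame in ratio_frames:
        flags = [uid for uid, r in frame.items() if r < threshold]
        per_frame.append(len(flags))
        ever.update(flags)
    return ever, len(ever), np.array(per_frame)


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def orientation_stats(state: SimulationState, pair_cutoff: float = 250.0,
                      n_bins: int = 12) -> OrientationStats:
    """Filament orientation histogram and antiparallel-pair fraction.

    Orientation is the pointed-to-barbed end-to-end unit vector; a pair of
    filaments whose midpoints lie within ``pair_cutoff`` is antiparallel
    when the dot product of their orientations is negative.
    """
    domain = state.domain
    fils = state.filaments
    ors = np.array([f.orientation(domain) for f in fils]) if fils else np.zeros((0, 3))
    az = np.mod(np.arctan2(ors[:, 1], ors[:, 0]), 2 * np.pi) if len(fils) else np.zeros(0)
    hist, edges = np.histogram(az, bins=n_bins, range=(0, 2 * np.pi))
    if len(fils) < 2:
        return OrientationStats(az, hist, edges, float("nan"), 0)
    mids = np.array([f.unwrapped(domain).mean(axis=0) for f in fils])
    mids[:, 1] %= domain.size_y
    d = mids[:, None, :] - mids[None, :, :]
    d[..., 1] -= domain.size_y * np.round(d[..., 1] / domain.size_y)
    dist2 = np.einsum("ijk,ijk->ij", d, d)
    iu, ju = np.triu_indices(len(fils), k=1)
    close = dist2[iu, ju] < pair_cutoff ** 2
    if not np.any(close):
        return OrientationStats(az, hist, edges, float("nan"), 0)
    dots = np.einsum("ij,ij->i", ors[iu[close]], ors[ju[close]])
    return OrientationStats(az, hist, edges, float(np.mean(dots < 0)),
                            int(close.sum()))


def antiparallel_fraction_y(state: SimulationState,
                            pair_cutoff: float = 250.0) -> float:
    """Fraction of nearby pairs antiparallel along y (opposite y signs)."""
    stats = orientation_stats(state, pair_cutoff)
    domain = state.domain
    fils = state.filaments
    if len(fils) < 2:
        return float("nan")
    ors = np.array([f.orientation(domain) for f in fils])
    mids = np.array([f.unwrapped(domain).mean(axis=0) for f in fils])
    mids[:, 1] %= domain.size_y
    d = mids[:, None, :] - mids[None, :, :]
    d[..., 1] -= domain.size_y * np.round(d[..., 1] / domain.size_y)
    dist2 = np.einsum("ijk,ijk->ij", d, d)
    iu, ju = np.triu_indices(len(fils), k=1)
    close = dist2[iu, ju] < pair_cutoff ** 2
    if not np.any(close):
        return float("nan")
    return float(np.mean(ors[iu[close], 1] * ors[ju[close], 1] < 0))


# ---------------------------------------------------------------------------
# persistence length
# ---------------------------------------------------------------------------

def adjacent_tangent_cosines(points: np.ndarray, domain: Domain) -> np.ndarray:
    """cos(theta) between consecutive segment tangents of one filament."""
    d = minimum_image(points[:-1], points[1:], domain)
    t = d / np.linalg.norm(d, axis=1)[:, None]
    return np.einsum("ij,ij->i", t[:-1], t[1:])


def persistence_length(mean_cos: float, bond_length: float) -> float:
    """Lp = -a / ln<cos theta> for a discrete chain with bond length a."""
    if not 0 < mean_cos < 1:
        raise ValueError("mean tangent cosine must lie in (0, 1)")
    return -bond_length / np.log(mean_cos)


# ---------------------------------------------------------------------------
# standard observer for the integration loop
# ---------------------------------------------------------------------------

def standard_observer(state: SimulationState, system=None) -> dict:
    row = {
        "tension": bundle_tension(state, system=system),
        "n_crosslinks": state.n_crosslinks,
        "n_bound_motor_arms": state.n_bound_motor_arms(),
    }
    try:
        row["sigma_x"] = sigma_x(state)
    except ValueError:
        row["sigma_x"] = float("nan")
    ratios = shape_ratios(state)
    row["n_buckled"] = sum(1 for r in ratios.values() if r < BUCKLING_THRESHOLD)
    row["min_shape_ratio"] = min(ratios.values()) if ratios else 1.0
    return row


def shape_ratio_observer(state: SimulationState, system=None) -> dict:
    return {"shape_ratios": shape_ratios(state)}
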