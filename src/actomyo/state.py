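"""Domain types: filaments, cross-linkers, motor ensembles, simulation state.

Filaments are ordered chains of endpoints (pointed end first, barbed end
last).  Binding sites are spaced every ``site_spacing`` (7 nm) along each
segment and indexed 0-based from the pointed side of the segment.  Monomeric
actin and unbound cross-linkers/motors are carried implicitly as pool counts;
actin mass (pool + polymerized) is conserved by every operation.
"""
from __future__ import annotations

import copy as _copy
import dataclasses
import itertools
from typing import Optional

import numpy as np

from .geometry import minimum_image, unwrap_chain
from .params import Domain, ParameterSet

_uid_counter = itertools.count(1)


def _next_uid() -> int:
    return next(_uid_counter)


Site = tuple  # (Filament, seg_index, site_index)


class Filament:
    """Polar chain of cylindrical actin segments.

    ``points`` has shape (n_segments + 1, 3); ``points[0]`` is the pointed
    end, ``points[-1]`` the barbed end.  ``occupancy`` maps
    (seg_index, site_index) -> (kind, owner, arm_index) for bound ACP and
    motor arms.
    """

    __slots__ = ("uid", "points", "occupancy", "created")

    def __init__(self, points, created: float = 0.0, uid: Optional[int] = None):
        self.points = np.array(points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2:
            raise ValueError("a filament needs at least one segment")
        self.occupancy: dict = {}
        self.created = created
        self.uid = _next_uid() if uid is None else uid

    @property
    def n_segments(self) -> int:
        return self.points.shape[0] - 1

    def site_fraction(self, site_index: int, params: ParameterSet) -> float:
        return site_index / params.sites_per_segment

    def site_position(self, seg: int, site: int, params: ParameterSet) -> np.ndarray:
        s = self.site_fraction(site, params)
        return (1.0 - s) * self.points[seg] + s * self.points[seg + 1]

    def segment_unit(self, seg: int, domain: Domain) -> np.ndarray:
        d = minimum_image(self.points[seg], self.points[seg + 1], domain)
        n = np.linalg.norm(d)
        return d / n if n > 0 else np.array([1.0, 0.0, 0.0])

    def unwrapped(self, domain: Domain) -> np.ndarray:
        return unwrap_chain(self.points, domain)

    def contour_length(self, domain: Domain) -> float:
        pts = self.unwrapped(domain)
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))

    def end_to_end(self, domain: Domain) -> float:
        pts = self.unwrapped(domain)
        return float(np.linalg.norm(pts[-1] - pts[0]))

    def shape_ratio(self, domain: Domain) -> float:
        c = self.contour_length(domain)
        return self.end_to_end(domain) / c if c > 0 else 1.0

    def orientation(self, domain: Domain) -> np.ndarray:
        """Pointed-to-barbed unit vector from the unwrapped end-to-end vector."""
        pts = self.unwrapped(domain)
        d = pts[-1] - pts[0]
        n = np.linalg.norm(d)
        return d / n if n > 0 else np.array([0.0, 1.0, 0.0])


class CrossLinker:
    """Two-armed actin cross-linking protein (ACP).

    The hinge point is explicit; each arm is either free (None) or bound to a
    site (filament, seg, site).  A functional cross-link requires the two
    arms on distinct filaments.
    """

    __slots__ = ("uid", "hinge", "sites")

    def __init__(self, hinge, uid: Optional[int] = None):
        self.hinge = np.array(hinge, dtype=float)
        self.sites: list = [None, None]
        self.uid = _next_uid() if uid is None else uid

    @property
    def n_bound(self) -> int:
        return sum(s is not None for s in self.sites)

    def bound_filaments(self):
        return [s[0] for s in self.sites if s is not None]


class MotorEnsemble:
    """Myosin thick-filament ensemble: a 3-segment backbone with 8 arms.

    The backbone has symmetric polarity; four arms anchor at each terminal
    backbone endpoint (point 0 and point 3).  Each arm aggregates ``n_heads``
    myosin heads and is either free or bound to one actin site.
    """

    __slots__ = ("uid", "points", "arm_anchor", "arm_site")

    def __init__(self, points, uid: Optional[int] = None, n_arms: int = 8):
        self.points = np.array(points, dtype=float)
        if self.points.shape != (4, 3):
            raise ValueError("motor backbone must have 4 endpoints (3 segments)")
        half = n_arms // 2
        self.arm_anchor = [0] * half + [3] * (n_arms - half)
        self.arm_site: list = [None] * n_arms
        self.uid = _next_uid() if uid is None else uid

    @property
    def n_arms(self) -> int:
        return len(self.arm_site)

    def anchor_point(self, arm: int) -> np.ndarray:
        return self.points[self.arm_anchor[arm]]


@dataclasses.dataclass
class SimulationState:
    """Complete mutable model state."""

    domain: Domain
    params: ParameterSet
    filaments: list
    acps: list
    motors: list
    monomer_pool: int
    free_acp: int
    free_motor: int
    time: float = 0.0
    rng: np.random.Generator = None
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.rng is None:
            self.rng = np.random.default_rng(0)

    # ---- bookkeeping --------------------------------------------------------

    @property
    def polymerized_monomers(self) -> int:
        mps = self.params.monomers_per_segment
        return sum(f.n_segments for f in self.filaments) * mps

    @property
    def total_monomers(self) -> int:
        return self.polymerized_monomers + self.monomer_pool

    @property
    def n_crosslinks(self) -> int:
        """ACPs whose two arms bridge two distinct filaments."""
        n = 0
        for a in self.acps:
            if a.n_bound == 2 and a.sites[0][0] is not a.sites[1][0]:
                n += 1
        return n

    def n_bound_motor_arms(self) -> int:
        return sum(sum(s is not None for s in m.arm_site) for m in self.motors)

    def filament_by_uid(self, uid: int):
        for f in self.filaments:
            if f.uid == uid:
                return f
        raise KeyError(uid)

    def mean_filament_length(self) -> float:
        if not self.filaments:
            return 0.0
        r0 = self.params.r0_actin
        return r0 * float(np.mean([f.n_segments for f in self.filaments]))

    def actin_points(self) -> np.ndarray:
        if not self.filaments:
            return np.zeros((0, 3))
        return np.concatenate([f.points for f in self.filaments])

    # ---- occupancy plumbing -------------------------------------------------

    def bind_site(self, site, kind: str, owner, arm: int) -> None:
        fil, seg, idx = site
        key = (seg, idx)
        if key in fil.occupancy:
            raise ValueError("binding site already occupied")
        fil.occupancy[key] = (kind, owner, arm)
        if kind == "acp":
            owner.sites[arm] = site
        else:
            owner.arm_site[arm] = site

    def unbind_site(self, site, kind: str, owner, arm: int) -> None:
        fil, seg, idx = site
        fil.occupancy.pop((seg, idx), None)
        if kind == "acp":
            owner.sites[arm] = None
        else:
            owner.arm_site[arm] = None

    def release_arms_on_segment(self, fil, seg: int) -> int:
        """Force-unbind every arm bound to sites on one segment."""
        released = 0
        for (s, idx) in [k for k in fil.occupancy if k[0] == seg]:
            kind, owner, arm = fil.occupancy.pop((s, idx))
            if kind == "acp":
                owner.sites[arm] = None
                if owner.n_bound == 0:
                    if owner in self.acps:
                        self.acps.remove(owner)
                    self.free_acp += 1
            else:
                owner.arm_site[arm] = None
            released += 1
        return released

    # ---- invariants ---------------------------------------------------------

    def validate(self) -> None:
        seen_total = self.total_monomers
        if seen_total < 0:
            raise AssertionError("negative actin mass")
        for f in self.filaments:
            if f.n_segments < 1:
                raise AssertionError("filament with no segments")
            for (seg, idx), (kind, owner, arm) in f.occupancy.items():
                if not (0 <= seg < f.n_segments):
                    raise AssertionError("occupancy refers to a missing segment")
                if not (0 <= idx < self.params.sites_per_segment):
                    raise AssertionError("occupancy refers to a missing site")
                site = owner.sites[arm] if kind == "acp" else owner.arm_site[arm]
                if site is None or site[0] is not f or site[1] != seg or site[2] != idx:
                    raise AssertionError("occupancy back-reference broken")
        for a in self.acps:
            for arm, site in enumerate(a.sites):
                if site is not None:
                    fil, seg, idx = site
                    if fil.occupancy.get((seg, idx)) != ("acp", a, arm):
                        raise AssertionError("ACP arm not registered in occupancy")
            fils = a.bound_filaments()
            if len(fils) == 2 and fils[0] is fils[1]:
                raise AssertionError("both ACP arms on one filament")
        for m in self.motors:
            for arm, site in enumerate(m.arm_site):
                if site is not None:
                    fil, seg, idx = site
                    if fil.occupancy.get((seg, idx)) != ("motor", m, arm):
                        raise AssertionError("motor arm not registered in occupancy")

    def copy(self) -> "SimulationState":
        return _copy.deepcopy(self)


def build_state(params: ParameterSet, domain: Domain, orientation="isotropic",
                seed: int = 0, **assembly_kwargs) -> SimulationState:
    """Assemble a network state (delegates to :mod:`actomyo.turnover`)."""
    from .turnover import assemble_network

    return assemble_network(params, domain, orientation, seed, **assembly_kwargs)
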