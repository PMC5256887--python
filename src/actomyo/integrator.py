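"""Overdamped Langevin integration and the main simulation loop.

Positions obey  zeta_i dr_i/dt = F_i + F_i^T  with Gaussian thermal forces
satisfying the fluctuation-dissipation relation
<F^T F^T> = 2 kBT zeta / dt per component, advanced by explicit Euler at
the fixed time step dt = 1.5e-5 s.  Mechanics run in a compiled kernel for
``kinetics_interval`` steps at a time; stochastic events (binding,
unbinding, walking, turnover) are evaluated between kernel calls.  Runs are
bitwise reproducible for a given initial state and seed.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np

from ._kernels import run_kernel
from .flatten import build_system, compute_forces, rebuild_repulsion_pairs, scatter
from .kinetics import MotorRateModel, kinetics_pass
from .params import Domain, ParameterSet
from .state import SimulationState


@dataclasses.dataclass
class StepSchedule:
    """Timing of the integration loop.

    ``kinetics_interval`` and ``neighbor_interval`` are in steps and passes
    respectively; ``record_interval`` is in steps (0 disables recording).
    """

    dt: float = 1.5e-5
    duration: float = 1.0
    kinetics_interval: int = 10
    record_interval: int = 3333     # ~0.05 s at the reference dt
    neighbor_interval: int = 10     # kinetics passes between neighbor rebuilds

    def __post_init__(self):
        if self.duration < 0 or self.dt <= 0:
            raise ValueError("duration must be >= 0 and dt > 0")
        if self.kinetics_interval < 1:
            raise ValueError("intervals must be >= 1 step")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


def thermal_force(zeta, kBT: float, dt: float, rng: np.random.Generator,
                  size=None):
    """Gaussian thermal force with variance 2 kBT zeta / dt per component."""
    amp = np.sqrt(2.0 * kBT * np.asarray(zeta, dtype=float) / dt)
    if size is None:
        size = np.shape(amp) + (3,) if np.ndim(amp) else (3,)
    return np.asarray(amp)[..., None] * rng.standard_normal(size) \
        if np.ndim(amp) else amp * rng.standard_normal(size)


def euler_step(P, F, zeta, dt: float, domain: Domain):
    """Reference single Euler step: r += F dt / zeta, y wrapped."""
    out = P + F * dt / np.asarray(zeta, dtype=float)[:, None]
    return domain.wrap_y(out)


_NO_NOISE = np.zeros((1, 1, 3))


class NaNError(RuntimeError):
    """Raised when positions become non-finite; carries a diagnostic dump."""

    def __init__(self, time, diagnostics):
        super().__init__(f"non-finite positions at t = {time:.6f} s")
        self.diagnostics = diagnostics


def run(state: SimulationState, schedule: StepSchedule,
        observers: Sequence[Callable] = (),
        model: Optional[MotorRateModel] = None,
        walking: bool = True, turnover: bool = True, binding: bool = True,
        thermal: bool = True,
        trajectory: Optional[list] = None) -> dict:
    """Advance the state by ``schedule.duration`` seconds.

    Observers are callables ``obs(state, system) -> dict`` invoked on the
    recording grid (including t = 0); their rows are collected into the
    returned dict of lists.  ``trajectory``, if given, receives a snapshot
    dict (time, per-filament unwrapped points and uids) at each record.
    """
    p = state.params
    domain = state.domain
    if model is None:
        model = state.meta.get("motor_model") or MotorRateModel.from_params(p)
    records: dict = {"time": []}

    def do_record():
        records["time"].append(state.time)
        for obs in observers:
            for key, val in obs(state, system).items():
                records.setdefault(key, []).append(val)
        if trajectory is not None:
            trajectory.append({
                "time": state.time,
                "uids": [f.uid for f in state.filaments],
                "points": [f.unwrapped(domain) for f in state.filaments],
            })

    system = build_system(state)
    rebuild_repulsion_pairs(system, domain, p)
    n_steps = schedule.n_steps
    record_every = schedule.record_interval
    if record_every:
        do_record()

    steps_done = 0
    passes = 0
    next_record = record_every if record_every else n_steps + 1
    while steps_done < n_steps:
        chunk = min(schedule.kinetics_interval, n_steps - steps_done)
        if record_every:
            chunk = min(chunk, next_record - steps_done)
        if thermal:
            noise = state.rng.standard_normal((chunk, system.P.shape[0], 3))
        else:
            noise = _NO_NOISE
        run_kernel(system.P, system.zeta, system.noise_amp, noise, chunk,
                   p.dt, domain.size_y,
                   system.springs_i, system.springs_f,
                   system.axial_i, system.axial_f,
                   system.angles_i, system.angles_f,
                   system.rep_pairs, p.kr_repulsion, p.rc_actin,
                   p.k_wall, domain.size_x, domain.size_z,
                   thermal)
        steps_done += chunk
        state.time += chunk * p.dt
        if not np.all(np.isfinite(system.P)):
            raise NaNError(state.time, {
                "n_points": int(system.P.shape[0]),
                "bad_points": int(np.sum(~np.isfinite(system.P).all(axis=1))),
            })
        scatter(system, state)
        passes += 1
        changed = kinetics_pass(state, chunk * p.dt, model=model,
                                walking=walking, binding=binding,
                                turnover=turnover, system=system)
        if changed:
            system = build_system(state)
            rebuild_repulsion_pairs(system, domain, p)
        elif passes % schedule.neighbor_interval == 0:
            rebuild_repulsion_pairs(system, domain, p)
        if record_every and steps_done >= next_record:
            do_record()
            next_record += record_every
    if record_every and (not records["time"] or records["time"][-1] < state.time):
        do_record()
    return records
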