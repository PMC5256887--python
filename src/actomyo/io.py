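"""Checkpoint and trajectory I/O.

State checkpoints are HDF5 files (groups /filaments, /acps, /motors,
/params, /rng) with a JSON metadata sidecar; observable tables are plain
CSV.  Checkpoints round-trip exactly: positions, binding topology, pools,
and the RNG state are restored bit for bit.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .params import Domain, ParameterSet
from .state import CrossLinker, Filament, MotorEnsemble, SimulationState

_KIND_CODE = {"acp": 0, "motor": 1}
_KIND_NAME = {v: k for k, v in _KIND_CODE.items()}


def save_state(state: SimulationState, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as h:
        h.attrs["time"] = state.time
        h.attrs["format_version"] = 1
        g = h.create_group("domain")
        for k in ("size_x", "size_y", "size_z"):
            g.attrs[k] = getattr(state.domain, k)
        g = h.create_group("params")
        for k, v in state.params.asdict().items():
            g.attrs[k] = v

        fils = state.filaments
        offsets = np.cumsum([0] + [f.points.shape[0] for f in fils])
        g = h.create_group("filaments")
        g.create_dataset("points", data=np.concatenate([f.points for f in fils])
                         if fils else np.zeros((0, 3)))
        g.create_dataset("offsets", data=offsets)
        g.create_dataset("uid", data=np.array([f.uid for f in fils], dtype=np.int64))
        g.create_dataset("created", data=np.array([f.created for f in fils]))

        rows = []
        for f in fils:
            for (seg, idx), (kind, owner, arm) in f.occupancy.items():
                rows.append((f.uid, seg, idx, _KIND_CODE[kind], owner.uid, arm))
        h.create_dataset("occupancy", data=np.array(rows, dtype=np.int64).reshape(-1, 6))

        g = h.create_group("acps")
        g.create_dataset("hinge", data=np.array([a.hinge for a in state.acps]).reshape(-1, 3))
        g.create_dataset("uid", data=np.array([a.uid for a in state.acps], dtype=np.int64))
        g = h.create_group("motors")
        g.create_dataset("points", data=np.array([m.points for m in state.motors]).reshape(-1, 4, 3))
        g.create_dataset("uid", data=np.array([m.uid for m in state.motors], dtype=np.int64))

        g = h.create_group("pools")
        g.attrs["monomer_pool"] = state.monomer_pool
        g.attrs["free_acp"] = state.free_acp
        g.attrs["free_motor"] = state.free_motor
        h.create_dataset("rng", data=json.dumps(state.rng.bit_generator.state))

    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {
        "time": state.time,
        "n_filaments": len(state.filaments),
        "n_acps": len(state.acps),
        "n_motors": len(state.motors),
        "params": state.params.asdict(),
        "meta": {k: v for k, v in state.meta.items() if _json_safe(v)},
    }
    sidecar.write_text(json.dumps(meta, indent=2, default=str))
    return path


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def load_state(path) -> SimulationState:
    with h5py.File(path, "r") as h:
        domain = Domain(**{k: float(h["domain"].attrs[k])
                           for k in ("size_x", "size_y", "size_z")})
        raw = dict(h["params"].attrs)
        fields = {f.name: f.type for f in dataclasses.fields(ParameterSet)}
        kwargs = {}
        for k, v in raw.items():
            if k not in fields:
                continue
            kwargs[k] = int(v) if fields[k] is int else (
                float(v) if fields[k] is float else v)
        params = ParameterSet(**kwargs)

        pts = h["filaments/points"][...]
        offs = h["filaments/offsets"][...]
        uids = h["filaments/uid"][...]
        created = h["filaments/created"][...]
        filaments = [Filament(pts[offs[i]:offs[i + 1]], created=float(created[i]),
                              uid=int(uids[i]))
                     for i in range(len(uids))]
        acps = [CrossLinker(hg, uid=int(u))
                for hg, u in zip(h["acps/hinge"][...], h["acps/uid"][...])]
        motors = [MotorEnsemble(pt, uid=int(u), n_arms=params.n_arms)
                  for pt, u in zip(h["motors/points"][...], h["motors/uid"][...])]

        state = SimulationState(
            domain=domain, params=params, filaments=filaments, acps=acps,
            motors=motors,
            monomer_pool=int(h["pools"].attrs["monomer_pool"]),
            free_acp=int(h["pools"].attrs["free_acp"]),
            free_motor=int(h["pools"].attrs["free_motor"]),
            time=float(h.attrs["time"]),
            rng=np.random.default_rng(0),
        )
        state.rng.bit_generator.state = json.loads(h["rng"][()].decode()
                                                   if isinstance(h["rng"][()], bytes)
                                                   else h["rng"][()])
        fil_by_uid = {f.uid: f for f in filaments}
        owner_by_uid = {a.uid: a for a in acps}
        owner_by_uid.update({m.uid: m for m in motors})
        for fuid, seg, idx, kind, ouid, arm in h["occupancy"][...]:
            fil = fil_by_uid[int(fuid)]
            owner = owner_by_uid[int(ouid)]
            state.bind_site((fil, int(seg), int(idx)), _KIND_NAME[int(kind)],
                            owner, int(arm))
    state.validate()
    return state


def save_observables(records: dict, path) -> Path:
    """Write an observable record dict (from integrator.run) as CSV."""
    import pandas as pd

    path = Path(path)
    pd.DataFrame({k: v for k, v in records.items()
                  if not any(isinstance(x, dict) for x in v)}).to_csv(path, index=False)
    return path


def save_trajectory(frames: list, path) -> Path:
    """Store trajectory snapshots (list of dicts from integrator.run)."""
    path = Path(path)
    with h5py.File(path, "w") as h:
        for i, fr in enumerate(frames):
            g = h.create_group(f"frame_{i:06d}")
            g.attrs["time"] = fr["time"]
            g.create_dataset("uids", data=np.asarray(fr["uids"], dtype=np.int64))
            pts = fr["points"]
            g.create_dataset("points", data=np.concatenate(pts) if pts else np.zeros((0, 3)))
            g.create_dataset("offsets",
                             data=np.cumsum([0] + [p.shape[0] for p in pts]))
    return path


def load_trajectory(path) -> list:
    frames = []
    with h5py.File(path, "r") as h:
        for name in sorted(h.keys()):
            g = h[name]
            pts = g["points"][...]
            offs = g["offsets"][...]
            frames.append({
                "time": float(g.attrs["time"]),
                "uids": list(g["uids"][...]),
                "points": [pts[offs[i]:offs[i + 1]] for i in range(len(offs) - 1)],
            })
    return frames
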