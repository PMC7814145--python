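"""Configuration, checkpoints and standard-format writers.

Time series go to CSV (pandas), field snapshots to legacy-ASCII VTK
structured points (readable by ParaView/VisIt), checkpoints to HDF5.
Every artifact written through :func:`run_header` carries the config hash
and the seed, so a run can be reproduced bit-for-bit from its output
directory.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .drqn import DRQNAgent, ReplayMemory, RLConfig, Transition


def load_config(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialisation."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def save_config(cfg: dict, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(cfg), fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_header(cfg: dict, seed) -> dict:
    return {"config_hash": config_hash(cfg), "seed": seed}


def write_timeseries_csv(path, columns: dict, header: dict | None = None):
    """CSV writer for diagnostics; a commented header line carries the
    config hash and seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(columns)
    with open(path, "w") as fh:
        if header:
            fh.write("# " + json.dumps(header) + "\n")
        df.to_csv(fh, index=False)


def read_timeseries_csv(path):
    return pd.read_csv(path, comment="#")


def write_vtk_structured(path, block, fields=None, header: dict | None = None):
    """Legacy-ASCII VTK structured-points snapshot of a lattice block.

    Writes density, velocity and the central-difference vorticity (the
    quantity plotted in the study's -4..4 contour maps) unless ``fields``
    supplies a custom dict of name -> 2D array."""
    rho, ux, uy, p = block.macroscopic()
    Cu = getattr(block, "_Cu", 1.0)
    if fields is None:
        dudy = np.gradient(ux, axis=0)
        dvdx = np.gradient(uy, axis=1)
        vort = (dvdx - dudy) / 1.0  # lattice units; dx = 1
        fields = {"density": rho, "vorticity": vort}
        vec = {"velocity": (ux, uy)}
    else:
        vec = {}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ny, nx = rho.shape
    with open(path, "w") as fh:
        title = "swimrl snapshot"
        if header:
            title += " " + json.dumps(header)
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(title[:255] + "\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} 1\n")
        fh.write(f"ORIGIN {block.x0} {block.y0} 0\n")
        fh.write(f"SPACING {block.dx} {block.dx} 1\n")
        fh.write(f"POINT_DATA {nx * ny}\n")
        for name, arr in fields.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr.reshape(-1, 1), fmt="%.6e")
        for name, (ax, ay) in vec.items():
            fh.write(f"VECTORS {name} float\n")
            flat = np.stack([ax.ravel(), ay.ravel(),
                             np.zeros(ax.size)], axis=1)
            np.savetxt(fh, flat, fmt="%.6e")


def write_marker_csv(path, s, X, U, header=None):
    """Marker dump: arc coordinate, position and velocity per snapshot."""
    write_timeseries_csv(
        path,
        {"s": s, "x": X[:, 0], "y": X[:, 1], "u": U[:, 0], "v": U[:, 1]},
        header,
    )


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_agent(path, agent: DRQNAgent, extra: dict | None = None):
    """Full training checkpoint: weights, Adam state, replay, rng state."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        h5.attrs["action_steps"] = agent.action_steps
        h5.attrs["config"] = json.dumps(agent.cfg.__dict__)
        h5.attrs["input_dim"] = agent.q.input_dim
        h5.attrs["n_actions"] = agent.n_actions
        if extra:
            h5.attrs["extra"] = json.dumps(extra, default=str)
        for i, p in enumerate(agent.q.parameters()):
            h5.create_dataset(f"q/{i}", data=p)
        for i, p in enumerate(agent.q_target.parameters()):
            h5.create_dataset(f"q_target/{i}", data=p)
        for i, m in enumerate(agent.opt.m):
            h5.create_dataset(f"adam/m{i}", data=m)
        for i, v in enumerate(agent.opt.v):
            h5.create_dataset(f"adam/v{i}", data=v)
        h5.attrs["adam_t"] = agent.opt.t
        buf = agent.replay._buf
        if buf:
            h5.create_dataset("replay/s", data=np.stack([t.s for t in buf]))
            h5.create_dataset("replay/a", data=np.array([t.a for t in buf]))
            h5.create_dataset("replay/r", data=np.array([t.r for t in buf]))
            h5.create_dataset("replay/s2",
                              data=np.stack([t.s_next for t in buf]))
            h5.create_dataset(
                "replay/term",
                data=np.array([t.terminal for t in buf], dtype=bool))
            h5.attrs["replay_pos"] = agent.replay._pos
        h5.attrs["rng_state"] = json.dumps(agent.rng.bit_generator.state)


def load_agent(path) -> DRQNAgent:
    with h5py.File(path, "r") as h5:
        cfg = RLConfig(**json.loads(h5.attrs["config"]))
        agent = DRQNAgent(int(h5.attrs["input_dim"]), int(h5.attrs["n_actions"]),
                          cfg)
        n = len(agent.q.parameters())
        agent.q.set_parameters([h5[f"q/{i}"][...] for i in range(n)])
        agent.q_target.set_parameters(
            [h5[f"q_target/{i}"][...] for i in range(n)])
        agent.opt.m = [h5[f"adam/m{i}"][...] for i in range(n)]
        agent.opt.v = [h5[f"adam/v{i}"][...] for i in range(n)]
        agent.opt.t = int(h5.attrs["adam_t"])
        agent.action_steps = int(h5.attrs["action_steps"])
        if "replay" in h5:
            s = h5["replay/s"][...]
            a = h5["replay/a"][...]
            r = h5["replay/r"][...]
            s2 = h5["replay/s2"][...]
            term = h5["replay/term"][...]
            agent.replay = ReplayMemory(cfg.replay_capacity)
            for k in range(len(a)):
                agent.replay._buf.append(
                    Transition(s[k], int(a[k]), float(r[k]), s2[k],
                               bool(term[k])))
            agent.replay._pos = int(h5.attrs["replay_pos"])
        agent.rng.bit_generator.state = json.loads(h5.attrs["rng_state"])
    return agent
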