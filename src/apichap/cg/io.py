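"""Plain-text trajectory output: XYZ frames + energies CSV + topology JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .integrate import Trajectory
from .system import CGSystem


def write_xyz(path, frames: np.ndarray, labels=None) -> None:
    frames = np.asarray(frames, dtype=float)
    n_beads = frames.shape[1]
    if labels is None:
        labels = ["CA"] * n_beads
    with open(path, "w") as fh:
        for fi, frame in enumerate(frames):
            fh.write(f"{n_beads}\nframe {fi}\n")
            for lab, (x, y, z) in zip(labels, frame):
                fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> np.ndarray:
    frames = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            fh.readline()  # comment
            coords = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                coords[i] = [float(v) for v in parts[1:4]]
            frames.append(coords)
    return np.array(frames)


def write_run(out_dir, system: CGSystem, trajectories: list[Trajectory],
              params=None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    topo = system.topology_summary()
    if params is not None:
        topo["sim_params"] = {k: getattr(params, k)
                              for k in ("T_reduced", "dt", "friction",
                                        "n_steps", "save_interval", "box",
                                        "n_replicas", "seed")}
    (out / "topology.json").write_text(json.dumps(topo, indent=1))
    for traj in trajectories:
        stem = f"replica_{traj.replica_id:02d}"
        write_xyz(out / f"{stem}.xyz", traj.frames)
        pd.DataFrame(traj.energies).to_csv(out / f"{stem}_energies.csv",
                                           index=False)


def read_run(run_dir):
    """Load (topology dict, list of frame arrays) from a run directory."""
    run = Path(run_dir)
    topo = json.loads((run / "topology.json").read_text())
    frames = [read_xyz(p) for p in sorted(run.glob("replica_*.xyz"))]
    if not frames:
        raise ValueError(f"no replica_*.xyz files under {run_dir}")
    return topo, frames
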