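"""Trajectory readers/writers: delimited text and a packed binary container.

Text format: a comment line ``# dt=<float> seed=<int> burn_in=<int>
model=<name>``, a header row naming the columns, then one state per row.
Floats are printed with 17 significant digits so the round trip is exact.
The binary container is a NumPy ``.npz`` archive with the same metadata.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .models import Trajectory

__all__ = ["write_trajectory", "read_trajectory"]


def write_trajectory(traj: Trajectory, path) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, states=traj.states, dt=traj.dt, seed=traj.seed,
                 burn_in=traj.burn_in_discarded, model_name=traj.model_name)
        return
    header = (f"dt={traj.dt!r} seed={traj.seed} burn_in={traj.burn_in_discarded} "
              f"model={traj.model_name}\n"
              + " ".join(f"x{i}" for i in range(traj.dim)))
    np.savetxt(path, traj.states, fmt="%.17g", header=header)


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            return Trajectory(states=z["states"], dt=float(z["dt"]),
                              seed=int(z["seed"]), burn_in_discarded=int(z["burn_in"]),
                              model_name=str(z["model_name"]))
    meta = {}
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise ValueError(f"{path}: missing '# dt=... seed=...' metadata line")
    for tok in first.lstrip("# ").split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    states = np.loadtxt(path, skiprows=2, ndmin=2)
    return Trajectory(states=states, dt=float(meta["dt"]), seed=int(meta["seed"]),
                      burn_in_discarded=int(meta.get("burn_in", 0)),
                      model_name=meta.get("model", ""))
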