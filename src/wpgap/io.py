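"""HDF5 / CSV persistence for trajectories, profiles and chains."""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd
import yaml

from .domain import build_disk, build_rectangle
from .model import FieldState
from .solver import Trajectory

__all__ = ["save_trajectory", "load_trajectory", "profile_to_csv",
           "save_chain", "load_chain"]

_FIELDS = ("u", "v", "G", "g")


def save_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory: /fields/{u,v,G,g}[time, ...grid], /meta."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("times", data=traj.times)
        grp = h5.create_group("fields")
        for name in _FIELDS:
            data = np.stack([getattr(s, name) for s in traj.states])
            grp.create_dataset(name, data=data, compression="gzip")
        for name, snaps in traj.modulator_states.items():
            grp.create_dataset(f"modulator_{name}",
                               data=np.stack(snaps), compression="gzip")
        meta = h5.create_group("meta")
        meta.attrs["yaml"] = yaml.safe_dump(traj.metadata)
        dom = traj.domain
        meta.attrs["geometry"] = dom.geometry
        if dom.is_polar:
            meta.attrs["R"] = dom.R
        else:
            meta.attrs["Lx"], meta.attrs["Ly"] = dom.Lx, dom.Ly
        meta.attrs["shape"] = dom.shape


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as h5:
        times = h5["times"][:]
        meta = yaml.safe_load(h5["meta"].attrs["yaml"])
        geometry = h5["meta"].attrs["geometry"]
        shape = tuple(int(v) for v in h5["meta"].attrs["shape"])
        if geometry == "polar-disk":
            dom = build_disk(R=float(h5["meta"].attrs["R"]),
                             n_phi=shape[0], n_r=shape[1])
        else:
            dom = build_rectangle(Lx=float(h5["meta"].attrs["Lx"]),
                                  Ly=float(h5["meta"].attrs["Ly"]),
                                  n_x=shape[0], n_y=shape[1])
        arrays = {name: h5["fields"][name][:] for name in _FIELDS}
        mods = {k.removeprefix("modulator_"): list(h5["fields"][k][:])
                for k in h5["fields"] if k.startswith("modulator_")}
    states = [FieldState(*[arrays[n][i] for n in _FIELDS],
                         t=float(times[i]), domain=dom)
              for i in range(len(times))]
    return Trajectory(times, states, dom, meta, mods)


def profile_to_csv(r: np.ndarray, values: np.ndarray, path,
                   name: str = "value") -> None:
    pd.DataFrame({"r": r, name: values}).to_csv(path, index=False)


def save_chain(chain: np.ndarray, names, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("chain", data=chain)
        h5.attrs["names"] = list(names)


def load_chain(path):
    with h5py.File(path, "r") as h5:
        return h5["chain"][:], list(h5.attrs["names"])
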