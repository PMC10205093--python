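"""Dataset bundle persistence (HDF5).

Layout:

* ``/meta`` attrs: ``dt_s``, format version;
* ``/trajectories/<id>``: datasets ``x``, ``s``, ``d``, ``phi``;
* ``/neurons/<id>``: dataset ``counts`` plus attrs ``label``, ``provenance``,
  ``traj``, optional generative parameters and split assignment.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .behavior import Trajectory
from .datasets import LabeledDataset, NeuronRecord
from .encoder import SimNeuronParams, SpikeTrain

__all__ = ["save_dataset", "load_dataset"]

FORMAT_VERSION = 1


def save_dataset(d: LabeledDataset, path, extra_meta: dict | None = None) -> None:
    """Write a labeled dataset (records + trajectories + splits) to HDF5."""
    # deduplicate trajectories shared across records
    traj_ids: dict[int, str] = {}
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["format_version"] = FORMAT_VERSION
        if len(d.neurons):
            meta.attrs["dt_s"] = d.neurons[0].traj.dt_s
        if extra_meta:
            meta.attrs["extra"] = json.dumps(extra_meta)
        gt = f.create_group("trajectories")
        gn = f.create_group("neurons")
        for rec in d.neurons:
            key = id(rec.traj)
            if key not in traj_ids:
                tid = f"t{len(traj_ids):05d}"
                traj_ids[key] = tid
                g = gt.create_group(tid)
                g.attrs["dt_s"] = rec.traj.dt_s
                g.create_dataset("x", data=rec.traj.x)
                g.create_dataset("s", data=rec.traj.s)
                g.create_dataset("d", data=rec.traj.d)
                g.create_dataset("phi", data=rec.traj.phi)
            g = gn.create_group(rec.neuron_id)
            g.create_dataset("counts", data=rec.spikes.counts)
            g.attrs["label"] = rec.label
            g.attrs["provenance"] = rec.provenance
            g.attrs["traj"] = traj_ids[key]
            if rec.neuron_id in d.split:
                g.attrs["split"] = d.split[rec.neuron_id]
            if rec.params is not None:
                p = rec.params
                g.attrs["params"] = json.dumps(
                    {
                        "class_id": p.class_id,
                        "alpha": p.alpha,
                        "a": None if np.isnan(p.a) else p.a,
                        "b": None if np.isnan(p.b) else p.b,
                        "gamma": p.gamma,
                        "eta": p.eta,
                    }
                )


def load_dataset(path) -> LabeledDataset:
    """Read a labeled dataset written by :func:`save_dataset`."""
    with h5py.File(path, "r") as f:
        trajs: dict[str, Trajectory] = {}
        for tid, g in f["trajectories"].items():
            trajs[tid] = Trajectory(
                dt_s=float(g.attrs["dt_s"]),
                x=g["x"][:],
                s=g["s"][:],
                d=g["d"][:],
                phi=g["phi"][:],
            )
        records = []
        split = {}
        for nid, g in f["neurons"].items():
            traj = trajs[g.attrs["traj"]]
            params = None
            if "params" in g.attrs:
                raw = json.loads(g.attrs["params"])
                params = SimNeuronParams(
                    class_id=int(raw["class_id"]),
                    alpha=float(raw["alpha"]),
                    a=np.nan if raw["a"] is None else float(raw["a"]),
                    b=np.nan if raw["b"] is None else float(raw["b"]),
                    gamma=float(raw["gamma"]),
                    eta=float(raw["eta"]),
                )
            records.append(
                NeuronRecord(
                    neuron_id=nid,
                    spikes=SpikeTrain(counts=g["counts"][:], dt_s=traj.dt_s),
                    traj=traj,
                    label=int(g.attrs["label"]),
                    provenance=str(g.attrs["provenance"]),
                    params=params,
                )
            )
            if "split" in g.attrs:
                split[nid] = str(g.attrs["split"])
    return LabeledDataset(neurons=records, split=split)
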