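"""Assemble classifier input windows from labeled datasets.

Each neuron becomes one multichannel sample: the spike-count series plus the
behavioral covariates relevant to the task, cropped to a fixed window length
(uniform random start within the session, seeded).  Channel sets follow the
incremental task definitions: the binary place/no-place task uses spike
counts and position; speed, direction and theta phase join as the class set
grows.
"""

from __future__ import annotations

import numpy as np

from .datasets import LabeledDataset

__all__ = ["CHANNELS_BY_CLASS_SET", "dataset_to_arrays", "channels_for"]

_CHANNEL_GETTERS = {
    "counts": lambda n: n.spikes.counts,
    "x": lambda n: n.traj.x,
    "s": lambda n: n.traj.s,
    "d": lambda n: n.traj.d,
    "phi": lambda n: n.traj.phi,
}

#: covariate channels used for each incremental class set
CHANNELS_BY_CLASS_SET = {
    (0, 1): ("counts", "x"),
    (0, 1, 2): ("counts", "x", "s"),
    (0, 1, 2, 3): ("counts", "x", "s", "d"),
    (0, 1, 2, 3, 4): ("counts", "x", "s", "d", "phi"),
}


def channels_for(classes) -> tuple:
    key = tuple(sorted(classes))
    if key not in CHANNELS_BY_CLASS_SET:
        raise ValueError(f"no channel convention for class set {key}")
    return CHANNELS_BY_CLASS_SET[key]


def dataset_to_arrays(
    d: LabeledDataset,
    channels,
    window_len: int,
    classes,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Build (X, Y): X of shape (N, M, window_len), Y one-hot over `classes`.

    Sessions longer than the window are cropped at a uniform random start
    (reproducible per seed); shorter sessions raise.
    """
    classes = sorted(classes)
    index = {c: k for k, c in enumerate(classes)}
    rng = np.random.default_rng(seed)
    N, M = len(d), len(channels)
    X = np.empty((N, M, window_len), dtype=np.float64)
    Y = np.zeros((N, len(classes)))
    for i, neuron in enumerate(d):
        T = neuron.traj.T
        if T < window_len:
            raise ValueError(
                f"neuron {neuron.neuron_id}: session length {T} shorter than "
                f"window {window_len}"
            )
        start = int(rng.integers(0, T - window_len + 1))
        sl = slice(start, start + window_len)
        for m, ch in enumerate(channels):
            X[i, m] = _CHANNEL_GETTERS[ch](neuron)[sl]
        if neuron.label not in index:
            raise ValueError(
                f"neuron {neuron.neuron_id} has label {neuron.label} outside "
                f"the class set {classes}"
            )
        Y[i, index[neuron.label]] = 1.0
    return X, Y
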