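"""Labeled neuron datasets and generative training-set augmentation.

Two augmentation schemes enlarge and balance a labeled dataset:

* **balanced augmentation** draws generative parameters from the theoretical
  per-class distributions (regardless of what was observed) until each class
  reaches a target count — the tool for balancing rare classes;
* **empirical augmentation** simulates new neurons from GLMs fitted to
  observed cells, enlarging the data without changing the distribution of
  observed spiking properties.

Augmentation never mutates or relabels base records; simulated records carry
their generating class as the label (label-by-construction) and a provenance
tag (``real`` | ``balanced_sim`` | ``empirical_sim``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .behavior import Trajectory, simulate_trajectory
from .encoder import (
    SimNeuronParams,
    SpikeTrain,
    draw_sim_params,
    sample_from_glm,
    sample_neuron,
)

__all__ = [
    "NeuronRecord",
    "LabeledDataset",
    "TrajectorySource",
    "shared_trajectory_source",
    "simulate_labeled_dataset",
    "balanced_augment",
    "empirical_augment",
    "split_dataset",
]

PROVENANCES = ("real", "balanced_sim", "empirical_sim")


@dataclass
class NeuronRecord:
    """One neuron: spike counts, its trajectory, a class label and provenance."""

    neuron_id: str
    spikes: SpikeTrain
    traj: Trajectory
    label: int
    provenance: str = "real"
    params: Optional[SimNeuronParams] = None

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")
        if not 0 <= self.label <= 4:
            raise ValueError("label must be a class id 0..4")
        if len(self.spikes) != self.traj.T:
            raise ValueError("spike train and trajectory lengths differ")


class TrajectorySource:
    """Seeded factory for per-neuron trajectories.

    Each call with a distinct seed yields an independent session with the
    given generator settings; the default emulates a 100 s W-track bout
    structure on the 10 ms grid.
    """

    def __init__(self, duration_s: float = 100.0, dt_s: float = 0.01, **kwargs):
        self.duration_s = duration_s
        self.dt_s = dt_s
        self.kwargs = kwargs

    def __call__(self, seed: int) -> Trajectory:
        return simulate_trajectory(
            self.duration_s, self.dt_s, seed=seed, **self.kwargs
        )


def shared_trajectory_source(traj: Trajectory) -> Callable[[int], Trajectory]:
    """A source that returns one fixed session for every neuron (the
    single-session mode where all simulated cells share covariates)."""
    return lambda seed: traj


@dataclass
class LabeledDataset:
    """A collection of labeled neuron records with optional split assignment."""

    neurons: list = field(default_factory=list)
    split: dict = field(default_factory=dict)  # neuron_id -> train|val|test

    def __len__(self) -> int:
        return len(self.neurons)

    def __iter__(self):
        return iter(self.neurons)

    @property
    def class_counts(self) -> dict:
        return dict(sorted(Counter(n.label for n in self.neurons).items()))

    @property
    def classes(self) -> list:
        return sorted({n.label for n in self.neurons})

    def labels(self) -> np.ndarray:
        return np.array([n.label for n in self.neurons], dtype=int)

    def one_hot(self, classes: Optional[Sequence[int]] = None) -> np.ndarray:
        """One-hot label matrix (N, K) over `classes` (defaults to observed)."""
        classes = list(classes) if classes is not None else self.classes
        index = {c: k for k, c in enumerate(classes)}
        Y = np.zeros((len(self.neurons), len(classes)))
        for i, n in enumerate(self.neurons):
            Y[i, index[n.label]] = 1.0
        return Y

    def subset(self, which: str) -> "LabeledDataset":
        """Records assigned to the given split ('train' | 'val' | 'test')."""
        if not self.split:
            raise ValueError("dataset has no split assignment")
        keep = [n for n in self.neurons if self.split.get(n.neuron_id) == which]
        return LabeledDataset(neurons=keep)

    def merged_with(self, other: "LabeledDataset") -> "LabeledDataset":
        return LabeledDataset(neurons=[*self.neurons, *other.neurons])


def _derive_seed(root_seed: int, counter: int) -> int:
    """Per-neuron stream seed derived from one root seed by counter offset."""
    return int(
        np.random.SeedSequence([root_seed & 0x7FFFFFFF, counter]).generate_state(1)[0]
        % (2**31)
    )


def simulate_labeled_dataset(
    per_class_counts: dict,
    traj_source: Callable[[int], Trajectory],
    rng_seed: int,
    provenance: str = "balanced_sim",
    id_prefix: str = "sim",
    allow_class4: bool = False,
) -> LabeledDataset:
    """Simulate a labeled dataset with the given per-class neuron counts."""
    records = []
    counter = 0
    for class_id in sorted(per_class_counts):
        for _ in range(per_class_counts[class_id]):
            s_par = _derive_seed(rng_seed, 3 * counter)
            s_trj = _derive_seed(rng_seed, 3 * counter + 1)
            s_spk = _derive_seed(rng_seed, 3 * counter + 2)
            params = draw_sim_params(class_id, s_par, allow_class4=allow_class4)
            traj = traj_source(s_trj)
            spikes = sample_neuron(params, traj, s_spk)
            records.append(
                NeuronRecord(
                    neuron_id=f"{id_prefix}-{rng_seed}-{counter:05d}",
                    spikes=spikes,
                    traj=traj,
                    label=class_id,
                    provenance=provenance,
                    params=params,
                )
            )
            counter += 1
    return LabeledDataset(neurons=records)


def balanced_augment(
    base: LabeledDataset,
    per_class_targets: dict,
    traj_source: Callable[[int], Trajectory],
    rng_seed: int,
    allow_class4: bool = False,
) -> LabeledDataset:
    """Add balanced-simulation neurons until each class reaches its target.

    Targets must not be below current counts.  Base records are shared, not
    copied or relabeled.
    """
    counts = base.class_counts
    needed = {}
    for class_id, target in per_class_targets.items():
        have = counts.get(class_id, 0)
        if target < have:
            raise ValueError(
                f"target {target} for class {class_id} below current count {have}"
            )
        if target > have:
            needed[class_id] = target - have
    extra = simulate_labeled_dataset(
        needed,
        traj_source,
        rng_seed,
        provenance="balanced_sim",
        id_prefix="bal",
        allow_class4=allow_class4,
    )
    return base.merged_with(extra)


def empirical_augment(
    base: LabeledDataset,
    fits: Sequence,
    n_new: int,
    traj_source: Callable[[int], Trajectory],
    rng_seed: int,
) -> LabeledDataset:
    """Add `n_new` neurons simulated from fitted GLMs (empirical augmentation).

    Each new neuron uses a fit drawn uniformly with replacement from the pool
    and is labeled with the fit's model class.
    """
    if len(fits) == 0:
        raise ValueError("empirical augmentation needs a nonempty fit pool")
    if n_new < 0:
        raise ValueError("n_new must be nonnegative")
    rng = np.random.default_rng(rng_seed)
    pick = rng.integers(0, len(fits), size=n_new)
    records = []
    for counter, k in enumerate(pick):
        fit = fits[int(k)]
        s_trj = _derive_seed(rng_seed, 2 * counter)
        s_spk = _derive_seed(rng_seed, 2 * counter + 1)
        traj = traj_source(s_trj)
        spikes = sample_from_glm(fit, traj, s_spk)
        records.append(
            NeuronRecord(
                neuron_id=f"emp-{rng_seed}-{counter:05d}",
                spikes=spikes,
                traj=traj,
                label=fit.class_id,
                provenance="empirical_sim",
            )
        )
    return base.merged_with(LabeledDataset(neurons=records))


def split_dataset(
    d: LabeledDataset,
    fractions: tuple = (0.7, 0.1, 0.2),
    seed: int = 0,
    stratified: bool = True,
) -> LabeledDataset:
    """Assign train/val/test splits (default 70/10/20), optionally per class.

    Returns a new dataset object sharing the records, with ``split`` filled;
    reproducible for a fixed seed.
    """
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be (train, val, test) summing to 1")
    rng = np.random.default_rng(seed)
    split: dict = {}

    def assign(ids: list) -> None:
        ids = list(ids)
        order = rng.permutation(len(ids))
        n = len(ids)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        n_val = min(n_val, n - n_train)
        for rank, j in enumerate(order):
            if rank < n_train:
                split[ids[j]] = "train"
            elif rank < n_train + n_val:
                split[ids[j]] = "val"
            else:
                split[ids[j]] = "test"

    if stratified:
        by_class: dict = {}
        for n in d.neurons:
            by_class.setdefault(n.label, []).append(n.neuron_id)
        for c in sorted(by_class):
            if len(by_class[c]) < 3:
                import warnings

                warnings.warn(
                    f"class {c} has fewer members than split groups; "
                    "best-effort assignment",
                    stacklevel=2,
                )
            assign(by_class[c])
    else:
        assign([n.neuron_id for n in d.neurons])
    return LabeledDataset(neurons=list(d.neurons), split=split)
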