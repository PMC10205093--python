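"""Scripted study designs: training-size scaling and augmentation curves.

Three experiment families, each fully synthetic and seed-reproducible:

* **scaling** — classification accuracy of each architecture as a function of
  balanced training-set size (binary place/no-place, or the 4-class place /
  speed / direction problem);
* **binary augmentation** — a base of class-1 "observed" stand-ins augmented
  with balanced simulated data (scenario 1), or a balanced simulated base
  augmented with class-1 stand-ins (scenario 2), evaluated on a fixed
  balanced 50+50 test set;
* **categorical augmentation** — a class-2 base augmented either with a
  balanced-simulation pool (case 1) or with a balanced pool whose class-2
  portion is generated by empirical augmentation from GLMs fitted to the base
  neurons (case 2), evaluated on a fixed balanced 3-class test set.

"Observed" neurons are synthetic stand-ins drawn from the class-appropriate
generative parameter distributions, so every design runs without any external
recording; an import path exists for users with real data.  Pool sizes follow
the reference design at ``scale=1.0`` (204 base neurons, 4584-neuron
categorical pools) and shrink proportionally for desk-scale runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datasets import (
    LabeledDataset,
    TrajectorySource,
    balanced_augment,
    empirical_augment,
    simulate_labeled_dataset,
)
from .nets import ClassifierSpec, TrainConfig, evaluate, train_classifier
from .ppglm import fit_class
from .windows import channels_for, dataset_to_arrays

__all__ = [
    "ExperimentReport",
    "run_scaling_experiment",
    "run_binary_augmentation_experiment",
    "run_categorical_augmentation_experiment",
    "export_report",
    "load_report",
]

#: reference "observed" base size (neurons)
BASE_N = 204
#: reference categorical augmentation pool (class 0, class 1, class 2)
CATEGORICAL_POOL = (1596, 1596, 1392)
#: fixed per-class test-set size
TEST_PER_CLASS = 50


@dataclass
class ExperimentReport:
    """Per-condition, per-replicate accuracies with full provenance."""

    design_id: str
    grid: list  # list of condition dicts
    rows: list = field(default_factory=list)  # dicts: condition + replicate + accuracy
    config_snapshot: dict = field(default_factory=dict)

    def accuracies(self, **condition) -> np.ndarray:
        sel = [
            r["accuracy"]
            for r in self.rows
            if all(r.get(k) == v for k, v in condition.items())
        ]
        return np.array(sel)

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        keys = [c for c in df.columns if c not in ("accuracy", "seed", "replicate")]
        return df.groupby(keys, as_index=False)["accuracy"].mean()


def _derive(seed: int, *path: int) -> int:
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, *path]).generate_state(1)[0] % (2**31))


def _train_eval(
    train_ds: LabeledDataset,
    test_ds: LabeledDataset,
    classes: Sequence[int],
    arch: str,
    window_len: int,
    seed: int,
    cfg: Optional[TrainConfig],
    arch_params: Optional[dict] = None,
) -> float:
    channels = channels_for(classes)
    Xtr, Ytr = dataset_to_arrays(train_ds, channels, window_len, classes, seed=_derive(seed, 11))
    Xte, Yte = dataset_to_arrays(test_ds, channels, window_len, classes, seed=_derive(seed, 12))
    spec = ClassifierSpec(
        arch=arch,
        n_channels=len(channels),
        window_len=window_len,
        n_classes=len(classes),
        arch_params=dict(arch_params or {}),
    )
    cfg = cfg or TrainConfig()
    cfg = TrainConfig(
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        rho=cfg.rho,
        seed=_derive(seed, 13),
    )
    clf = train_classifier(spec, Xtr, Ytr, cfg=cfg)
    acc, _ = evaluate(clf, Xte, Yte)
    return acc


def _default_source(window_len: int, dt_s: float = 0.01) -> TrajectorySource:
    return TrajectorySource(duration_s=window_len * dt_s, dt_s=dt_s)


def run_scaling_experiment(
    class_set: Sequence[int],
    size_grid: Sequence[float],
    archs: Sequence[str] = ("mcdcnn",),
    replicates: int = 3,
    seed: int = 0,
    window_len: int = 10_000,
    cfg: Optional[TrainConfig] = None,
    mcdcnn_preset: tuple = (3, 2),
) -> ExperimentReport:
    """Accuracy vs balanced training-set size for each architecture.

    ``size_grid`` entries are fractions of the reference size (204 neurons
    per class for the binary task and the 4-class task alike); each condition
    simulates a balanced training set of that size plus a balanced test set a
    quarter as large (the 80/20 train/test split of the design).
    """
    classes = sorted(class_set)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if any(f <= 0 for f in size_grid):
        raise ValueError("size fractions must be positive")
    per_class_full = BASE_N if len(classes) == 2 else BASE_N
    source = _default_source(window_len)
    grid, rows = [], []
    for frac in size_grid:
        n_per = max(int(round(frac * per_class_full)), 2)
        n_test = max(n_per // 4, 1)
        for arch_i, arch in enumerate(archs):
            grid.append({"size_frac": frac, "arch": arch})
            for rep in range(replicates):
                s = _derive(seed, int(frac * 1e6), arch_i, rep)
                train_ds = simulate_labeled_dataset(
                    {c: n_per for c in classes}, source, _derive(s, 1)
                )
                test_ds = simulate_labeled_dataset(
                    {c: n_test for c in classes}, source, _derive(s, 2)
                )
                acc = _train_eval(
                    train_ds, test_ds, classes, arch, window_len, s, cfg,
                    arch_params={"filters": mcdcnn_preset[0], "kernel": mcdcnn_preset[1]}
                    if arch == "mcdcnn"
                    else None,
                )
                rows.append(
                    {
                        "size_frac": frac,
                        "arch": arch,
                        "n_train": n_per * len(classes),
                        "replicate": rep,
                        "seed": s,
                        "accuracy": acc,
                    }
                )
    return ExperimentReport(
        design_id=f"scaling-{len(classes)}class",
        grid=grid,
        rows=rows,
        config_snapshot={
            "class_set": classes,
            "size_grid": list(size_grid),
            "archs": list(archs),
            "replicates": replicates,
            "seed": seed,
            "window_len": window_len,
            "epochs": (cfg or TrainConfig()).epochs,
        },
    )


def _observed_stand_ins(
    class_id: int, n: int, source, seed: int
) -> LabeledDataset:
    """Synthetic stand-ins for observed neurons of a given class."""
    ds = simulate_labeled_dataset({class_id: n}, source, seed, id_prefix="obs")
    for rec in ds.neurons:
        rec.provenance = "real"  # stand-in for an observed cell
    return ds


def run_binary_augmentation_experiment(
    scenario: int,
    fraction_grid: Sequence[float],
    replicates: int = 3,
    seed: int = 0,
    scale: float = 1.0,
    window_len: int = 10_000,
    cfg: Optional[TrainConfig] = None,
) -> ExperimentReport:
    """Binary place/no-place accuracy vs augmentation fraction.

    Scenario 1: a fixed base of class-1 observed stand-ins (204 at full
    scale) augmented with balanced simulated data (half class 0, half class
    1) at each grid fraction of the base size.  Scenario 2: a fixed balanced
    simulated base (102 + 102 at full scale) augmented with class-1 observed
    stand-ins.  The test set is fixed at 50 + 50 neurons per replicate.
    """
    if scenario not in (1, 2):
        raise ValueError("scenario must be 1 or 2")
    classes = (0, 1)
    base_n = max(int(round(BASE_N * scale)), 4)
    test_n = max(int(round(TEST_PER_CLASS * scale)), 5)
    source = _default_source(window_len)
    grid, rows = [], []
    for frac in fraction_grid:
        grid.append({"fraction": frac, "scenario": scenario})
        n_add = int(round(frac * base_n))
        for rep in range(replicates):
            s = _derive(seed, scenario, int(frac * 1e6), rep)
            if scenario == 1:
                train_ds = _observed_stand_ins(1, base_n, source, _derive(s, 1))
                counts = train_ds.class_counts
                train_ds = balanced_augment(
                    train_ds,
                    {
                        0: counts.get(0, 0) + n_add // 2,
                        1: counts.get(1, 0) + (n_add - n_add // 2),
                    },
                    source,
                    _derive(s, 2),
                )
            else:
                train_ds = simulate_labeled_dataset(
                    {0: base_n // 2, 1: base_n - base_n // 2}, source, _derive(s, 1)
                )
                train_ds = train_ds.merged_with(
                    _observed_stand_ins(1, n_add, source, _derive(s, 2))
                )
            test_ds = simulate_labeled_dataset(
                {0: test_n}, source, _derive(s, 3)
            ).merged_with(_observed_stand_ins(1, test_n, source, _derive(s, 4)))
            acc = _train_eval(
                train_ds, test_ds, classes, "mcdcnn", window_len, s, cfg,
                arch_params={"filters": 3, "kernel": 2},
            )
            rows.append(
                {
                    "scenario": scenario,
                    "fraction": frac,
                    "n_train": len(train_ds),
                    "replicate": rep,
                    "seed": s,
                    "accuracy": acc,
                }
            )
    return ExperimentReport(
        design_id=f"binary-augmentation-scenario{scenario}",
        grid=grid,
        rows=rows,
        config_snapshot={
            "scenario": scenario,
            "fraction_grid": list(fraction_grid),
            "replicates": replicates,
            "seed": seed,
            "scale": scale,
            "window_len": window_len,
            "epochs": (cfg or TrainConfig()).epochs,
        },
    )


def run_categorical_augmentation_experiment(
    case: int,
    fraction_grid: Sequence[float],
    replicates: int = 3,
    seed: int = 0,
    scale: float = 1.0,
    window_len: int = 10_000,
    cfg: Optional[TrainConfig] = None,
) -> ExperimentReport:
    """Three-class accuracy vs augmentation fraction for the two pool types.

    Both cases start from a base of class-2 observed stand-ins (204 at full
    scale).  Case 1 adds fractions of a balanced-simulation pool (1596 /
    1596 / 1392 neurons of classes 0/1/2 at full scale).  Case 2 adds
    fractions of a pool of the same size whose class-2 portion (1392 at full
    scale) comes from empirical augmentation: spike trains simulated from
    class-2 GLMs fitted to the base neurons.  The test set is fixed at 50
    neurons per class.
    """
    if case not in (1, 2):
        raise ValueError("case must be 1 or 2")
    classes = (0, 1, 2)
    base_n = max(int(round(BASE_N * scale)), 4)
    test_n = max(int(round(TEST_PER_CLASS * scale)), 5)
    pool = tuple(max(int(round(n * scale)), 2) for n in CATEGORICAL_POOL)
    source = _default_source(window_len)
    grid, rows = [], []
    for frac in fraction_grid:
        grid.append({"fraction": frac, "case": case})
        for rep in range(replicates):
            s = _derive(seed, 100 + case, int(frac * 1e6), rep)
            base = _observed_stand_ins(2, base_n, source, _derive(s, 1))
            n0, n1, n2 = (int(round(frac * n)) for n in pool)
            if case == 1:
                train_ds = balanced_augment(
                    base,
                    {0: n0, 1: n1, 2: base_n + n2},
                    source,
                    _derive(s, 2),
                )
            else:
                train_ds = balanced_augment(
                    base, {0: n0, 1: n1}, source, _derive(s, 2)
                )
                if n2 > 0:
                    fits = [
                        fit_class(2, rec.spikes, rec.traj) for rec in base.neurons
                    ]
                    train_ds = empirical_augment(
                        train_ds, fits, n2, source, _derive(s, 3)
                    )
            test_ds = simulate_labeled_dataset(
                {0: test_n, 1: test_n}, source, _derive(s, 4)
            ).merged_with(_observed_stand_ins(2, test_n, source, _derive(s, 5)))
            acc = _train_eval(
                train_ds, test_ds, classes, "mcdcnn", window_len, s, cfg,
                arch_params={"filters": 3, "kernel": 2},
            )
            rows.append(
                {
                    "case": case,
                    "fraction": frac,
                    "n_train": len(train_ds),
                    "replicate": rep,
                    "seed": s,
                    "accuracy": acc,
                }
            )
    return ExperimentReport(
        design_id=f"categorical-augmentation-case{case}",
        grid=grid,
        rows=rows,
        config_snapshot={
            "case": case,
            "fraction_grid": list(fraction_grid),
            "replicates": replicates,
            "seed": seed,
            "scale": scale,
            "window_len": window_len,
            "epochs": (cfg or TrainConfig()).epochs,
        },
    )


def export_report(report: ExperimentReport, path) -> tuple:
    """Write the result rows as CSV plus a JSON config snapshot for reruns."""
    if not report.rows:
        raise ValueError("report has no result rows")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    csv_path = path / f"{report.design_id}.csv"
    json_path = path / f"{report.design_id}.json"
    pd.DataFrame(report.rows).to_csv(csv_path, index=False)
    json_path.write_text(
        json.dumps(
            {
                "design_id": report.design_id,
                "grid": report.grid,
                "config_snapshot": report.config_snapshot,
            },
            indent=2,
        )
    )
    return csv_path, json_path


def load_report(csv_path, json_path) -> ExperimentReport:
    """Round-trip reader for :func:`export_report` output."""
    meta = json.loads(Path(json_path).read_text())
    rows = pd.read_csv(csv_path).to_dict(orient="records")
    return ExperimentReport(
        design_id=meta["design_id"],
        grid=meta["grid"],
        rows=rows,
        config_snapshot=meta["config_snapshot"],
    )
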