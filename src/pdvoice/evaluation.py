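"""Experiment protocols: repeated 50-50 splits, fixed splits, and the SAE grid.

Two evaluation modes are supported, matching how the two emulated corpora
are customarily used:

* ``repeated_split`` — a stratified 50-50 train/test partition re-randomised
  on every one of (by default) 10 repeats, reported as max/mean/min of each
  index over the repeats;
* ``fixed_split`` — a predefined train/test pair evaluated as-is; repeats
  re-seed only the stochastic pipeline stages (SAE initialisation and batch
  order), since the partition is fixed.

Each repeat runs the full pipeline with no leakage: min-max scaling and the
median imputation statistics are fitted on the training half only, then the
optional stacked-autoencoder reduction, then the vote-KNN classifier.  The
3x3 grid over hidden-layer sizes {10, 9, 8} x {8, 7, 6} is explored by
:func:`grid_search`, ranked by mean test accuracy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

from . import sae as sae_mod
from .dataset import LabeledDataset
from .knn import VoteKNN
from .metrics import all_metrics, confusion
from .sae import SAEConfig

__all__ = [
    "Protocol",
    "GridSpec",
    "EvalReport",
    "derive_run_seed",
    "split",
    "run_pipeline",
    "grid_search",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "f_score", "mcc")


@dataclass(frozen=True)
class Protocol:
    """Evaluation protocol parameters."""

    mode: str = "repeated_split"
    train_fraction: float = 0.5
    repeats: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("repeated_split", "fixed_split"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class GridSpec:
    """Hidden-size grid for the two-stage stack."""

    layer1_sizes: tuple[int, ...] = (10, 9, 8)
    layer2_sizes: tuple[int, ...] = (8, 7, 6)

    def __post_init__(self) -> None:
        if not self.layer1_sizes or not self.layer2_sizes:
            raise ValueError("grid axes must be non-empty")
        if any(s < 1 for s in self.layer1_sizes + self.layer2_sizes):
            raise ValueError("layer sizes must be >= 1")

    def cells(self) -> list[tuple[int, int]]:
        return [(l1, l2) for l1 in self.layer1_sizes for l2 in self.layer2_sizes]


@dataclass
class EvalReport:
    """Per-run metric records plus max/mean/min aggregates for one config."""

    config: dict
    runs: list[dict[str, float]]
    run_seeds: list[int]

    def __post_init__(self) -> None:
        if len(self.runs) != len(self.run_seeds):
            raise ValueError("one seed per run required")

    def summary(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for name in METRIC_NAMES:
            values = np.array([run[name] for run in self.runs])
            out[name] = {
                "max": float(values.max()),
                "mean": float(values.mean()),
                "min": float(values.min()),
            }
        return out

    def to_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"config": self.config.get("name", "pipeline")}
        for metric, agg in self.summary().items():
            for stat in ("max", "mean", "min"):
                row[f"{metric}_{stat}"] = agg[stat]
        return row


def derive_run_seed(master_seed: int, run_index: int) -> int:
    """Per-run seed derived reproducibly from the master seed."""
    return int(np.random.SeedSequence([master_seed, run_index]).generate_state(1)[0] % (2**31))


def split(
    data: LabeledDataset, protocol: Protocol, run_index: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Disjoint, exhaustive train/test partition for one repeat.

    Stratified by class by default; within each class the training half gets
    the ceiling of fraction * class size.  Deterministic per
    (protocol.seed, run_index).
    """
    rng = np.random.default_rng(np.random.SeedSequence([protocol.seed, run_index]))
    n = data.n_rows
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    if protocol.stratified:
        for cls in np.unique(data.labels):
            members = np.flatnonzero(data.labels == cls)
            if members.size < 2:
                raise ValueError(
                    f"class {cls} has {members.size} row(s); stratified split needs >= 2"
                )
            perm = rng.permutation(members)
            n_train = int(np.ceil(protocol.train_fraction * members.size))
            train_idx.append(perm[:n_train])
            test_idx.append(perm[n_train:])
    else:
        perm = rng.permutation(n)
        n_train = int(np.ceil(protocol.train_fraction * n))
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return (
        data.subset(np.sort(np.concatenate(train_idx))),
        data.subset(np.sort(np.concatenate(test_idx))),
    )


def _run_once(
    train: LabeledDataset,
    test: LabeledDataset,
    sae_config: SAEConfig | None,
    n_neighbors: int,
    metric: str,
    run_seed: int,
) -> dict[str, float]:
    medians = np.nanmedian(train.features, axis=0)
    x_train = train.impute_median(medians).features
    x_test = test.impute_median(medians).features

    scaler = MinMaxScaler().fit(x_train)
    x_train = scaler.transform(x_train)
    x_test = scaler.transform(x_test)

    if sae_config is not None:
        cfg = dataclasses.replace(sae_config, seed=run_seed)
        model = sae_mod.stack_train(x_train, cfg, labels=train.labels, scale=False)
        x_train = sae_mod.transform(model, x_train)
        x_test = sae_mod.transform(model, x_test)

    clf = VoteKNN(n_neighbors=n_neighbors, metric=metric).fit(x_train, train.labels)
    predictions = clf.predict(x_test)
    return all_metrics(confusion(test.labels, predictions))


def run_pipeline(
    data: LabeledDataset | tuple[LabeledDataset, LabeledDataset],
    protocol: Protocol,
    sae_config: SAEConfig | None = None,
    n_neighbors: int = 1,
    metric: str = "euclidean",
    name: str | None = None,
) -> EvalReport:
    """Evaluate scale -> (optional SAE) -> KNN under the given protocol.

    ``data`` is a single dataset for ``repeated_split`` or a (train, test)
    pair for ``fixed_split``.  A failing repeat propagates its error; no run
    is silently skipped.
    """
    fixed = isinstance(data, tuple)
    if fixed != (protocol.mode == "fixed_split"):
        raise ValueError(
            "fixed_split mode requires a (train, test) pair; repeated_split a single dataset"
        )
    runs: list[dict[str, float]] = []
    seeds: list[int] = []
    for r in range(protocol.repeats):
        run_seed = derive_run_seed(protocol.seed, r)
        if fixed:
            train, test = data
        else:
            train, test = split(data, protocol, r)
        runs.append(_run_once(train, test, sae_config, n_neighbors, metric, run_seed))
        seeds.append(run_seed)
    if name is None:
        name = (
            "knn" if sae_config is None else "sae-" + "-".join(map(str, sae_config.layer_sizes))
        )
    config = {
        "name": name,
        "sae_layer_sizes": None if sae_config is None else list(sae_config.layer_sizes),
        "n_neighbors": n_neighbors,
        "metric": metric,
        "protocol": dataclasses.asdict(protocol),
    }
    return EvalReport(config=config, runs=runs, run_seeds=seeds)


def grid_search(
    data: LabeledDataset | tuple[LabeledDataset, LabeledDataset],
    grid: GridSpec,
    protocol: Protocol,
    base_sae_config: SAEConfig | None = None,
    n_neighbors: int = 1,
    metric: str = "euclidean",
) -> list[EvalReport]:
    """One report per grid cell, ranked by mean test accuracy (descending).

    The ranking criterion is the mean accuracy over repeats; the full table
    is retained, so no cell is discarded.  Stable order under ties.
    """
    base = base_sae_config or SAEConfig()
    reports = []
    for l1, l2 in grid.cells():
        cfg = dataclasses.replace(base, layer_sizes=(l1, l2))
        reports.append(
            run_pipeline(
                data,
                protocol,
                sae_config=cfg,
                n_neighbors=n_neighbors,
                metric=metric,
                name=f"sae-{l1}-{l2}",
            )
        )
    reports.sort(key=lambda rep: -rep.summary()["accuracy"]["mean"])
    return reports


def reports_to_frame(reports: list[EvalReport] | EvalReport) -> pd.DataFrame:
    """Tabular max/mean/min layout: one row per pipeline configuration."""
    if isinstance(reports, EvalReport):
        reports = [reports]
    return pd.DataFrame([rep.to_row() for rep in reports])
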