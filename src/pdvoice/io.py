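"""Readers and writers: WAV audio, feature tables, reports, pipeline bundles.

All on-disk formats are plain text except WAV: feature tables and reports
are delimited text with a header (comma-separated by default; readers accept
semicolon or tab via the ``sep`` argument), and a trained pipeline persists
as a single self-describing JSON bundle (scaler statistics, optional SAE
stage parameters, the verbatim KNN training set, the feature schema and
provenance).  JSON stores floats at full ``repr`` precision, so a bundle
round-trips bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .dataset import LabeledDataset
from .evaluation import EvalReport, reports_to_frame
from .features import VoiceRecording
from .knn import VoteKNN
from .sae import SAEConfig, SAEModel
from . import sae as sae_mod

logger = logging.getLogger("pdvoice")

__all__ = [
    "FeatureTableSchema",
    "PipelineBundle",
    "read_wav",
    "write_wav",
    "read_feature_table",
    "write_feature_table",
    "write_report",
    "train_bundle",
    "save_bundle",
    "load_bundle",
]

BUNDLE_FORMAT = "pdvoice-bundle"
BUNDLE_VERSION = 1

_PCM_SCALE = {np.dtype(np.int16): 32768.0, np.dtype(np.int32): 2147483648.0}


@dataclass(frozen=True)
class FeatureTableSchema:
    """Column layout of a delimited feature table.

    ``label_encoding`` maps the raw label cell values to the binary classes
    (positive = PD = 1).  ``id_column`` names an optional subject identifier
    excluded from the feature matrix.
    """

    feature_columns: tuple[str, ...]
    label_column: str = "status"
    id_column: str | None = None
    positive_value: object = 1
    negative_value: object = 0

    def __post_init__(self) -> None:
        if len(self.feature_columns) < 1:
            raise ValueError("schema needs at least one feature column")
        names = self.feature_columns + (self.label_column,)
        if self.id_column is not None:
            names = names + (self.id_column,)
        if len(set(names)) != len(names):
            raise ValueError("schema column names must be unique")


# ---------------------------------------------------------------------------
# WAV


def read_wav(path) -> VoiceRecording:
    """Read a PCM or float WAV file as a mono recording in [-1, 1].

    Integer PCM is scaled by its full-scale value; stereo is downmixed by
    channel averaging (logged).  Unsupported or truncated files raise a
    ``ValueError`` naming the problem rather than returning partial data.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError on bad chunks
        raise ValueError(f"cannot decode {path} as WAV PCM/float: {exc}") from exc
    if data.dtype == np.dtype(np.uint8):
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype in (np.dtype(np.float32), np.dtype(np.float64)):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype} in {path}")
    if samples.ndim == 2:
        logger.info("downmixing %d-channel file %s to mono by averaging", samples.shape[1], path)
        samples = samples.mean(axis=1)
    if samples.size == 0:
        raise ValueError(f"{path} contains no samples")
    return VoiceRecording(samples=samples, rate=float(rate))


def write_wav(path, rec: VoiceRecording) -> None:
    """Write a recording as 16-bit PCM WAV."""
    scaled = np.clip(rec.samples, -1.0, 1.0)
    wavfile.write(Path(path), int(round(rec.rate)), np.round(scaled * 32767.0).astype(np.int16))


# ---------------------------------------------------------------------------
# feature tables


def read_feature_table(
    path, schema: FeatureTableSchema | None = None, sep: str = ","
) -> LabeledDataset:
    """Read a delimited feature table into a labelled dataset.

    Without a schema the last column is the label (must be binary 0/1), a
    leading non-numeric column is treated as the subject id, and everything
    between is a feature.  Non-numeric feature cells raise an error naming
    the offending row and column.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=sep)
    if frame.shape[0] == 0:
        raise ValueError(f"{path}: zero data rows")
    if schema is None:
        label_column = frame.columns[-1]
        id_column = None
        first = frame.columns[0]
        if frame[first].dtype == object:
            id_column = first
        feature_columns = tuple(
            c for c in frame.columns if c not in (label_column, id_column)
        )
        schema = FeatureTableSchema(
            feature_columns=feature_columns, label_column=label_column, id_column=id_column
        )
    missing = [
        c
        for c in schema.feature_columns + (schema.label_column,)
        if c not in frame.columns
    ]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    features = np.empty((frame.shape[0], len(schema.feature_columns)))
    for j, column in enumerate(schema.feature_columns):
        values = pd.to_numeric(frame[column], errors="coerce")
        original = frame[column]
        bad = values.isna() & original.notna() & (original.astype(str).str.strip() != "")
        bad &= ~original.astype(str).str.lower().isin(("nan",))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {original.iloc[row]!r} at row {row}, column {column!r}"
            )
        features[:, j] = values.to_numpy(dtype=np.float64)

    raw_labels = frame[schema.label_column]
    labels = np.empty(frame.shape[0], dtype=np.int64)
    pos, neg = schema.positive_value, schema.negative_value
    for i, value in enumerate(raw_labels):
        if value == pos:
            labels[i] = 1
        elif value == neg:
            labels[i] = 0
        else:
            raise ValueError(
                f"{path}: label {value!r} at row {i} is neither positive ({pos!r})"
                f" nor negative ({neg!r})"
            )
    subject_ids = (
        frame[schema.id_column].to_numpy() if schema.id_column is not None else None
    )
    return LabeledDataset(
        features=features,
        labels=labels,
        feature_names=schema.feature_columns,
        subject_ids=subject_ids,
    )


def write_feature_table(dataset: LabeledDataset, path, label_column: str = "status") -> None:
    """Write a dataset as comma-separated text with a header row."""
    dataset.to_frame(label_column=label_column).to_csv(Path(path), index=False)


def write_report(reports, path_prefix) -> tuple[Path, Path]:
    """Persist evaluation reports as ``<prefix>.csv`` and ``<prefix>.json``.

    The CSV mirrors the max/mean/min table layout (one row per pipeline
    configuration); the JSON keeps every per-run value and seed for audit.
    """
    if isinstance(reports, EvalReport):
        reports = [reports]
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    reports_to_frame(reports).to_csv(csv_path, index=False)
    payload = [
        {"config": rep.config, "runs": rep.runs, "run_seeds": rep.run_seeds,
         "summary": rep.summary()}
        for rep in reports
    ]
    json_path.write_text(json.dumps(payload, indent=1))
    return csv_path, json_path


# ---------------------------------------------------------------------------
# pipeline bundle


@dataclass
class PipelineBundle:
    """Everything needed to reproduce predictions: scaler + SAE + KNN data.

    ``predict`` refuses feature matrices whose width (or, when given a
    dataset, whose column names) do not match the training schema.
    """

    feature_names: tuple[str, ...]
    scaler_min: np.ndarray
    scaler_range: np.ndarray
    medians: np.ndarray
    train_features: np.ndarray
    train_labels: np.ndarray
    n_neighbors: int = 1
    metric: str = "euclidean"
    sae: SAEModel | None = None
    provenance: dict = field(default_factory=dict)

    def _classifier(self) -> VoteKNN:
        x = self._reduce(self.train_features)
        return VoteKNN(n_neighbors=self.n_neighbors, metric=self.metric).fit(
            x, self.train_labels
        )

    def _reduce(self, features: np.ndarray) -> np.ndarray:
        x = np.where(np.isnan(features), self.medians, features)
        x = (x - self.scaler_min) / self.scaler_range
        if self.sae is not None:
            x = sae_mod.transform(self.sae, x)
        return x

    def predict(self, data: LabeledDataset | np.ndarray) -> np.ndarray:
        if isinstance(data, LabeledDataset):
            if data.feature_names != self.feature_names:
                raise ValueError(
                    f"schema mismatch: bundle was trained on {len(self.feature_names)}"
                    f" features {list(self.feature_names)[:4]}..., got"
                    f" {len(data.feature_names)} features"
                )
            features = data.features
        else:
            features = np.atleast_2d(np.asarray(data, dtype=np.float64))
            if features.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"schema mismatch: expected {len(self.feature_names)} feature"
                    f" columns, got {features.shape[1]}"
                )
        return self._classifier().predict(self._reduce(features))


def train_bundle(
    train: LabeledDataset,
    sae_config: SAEConfig | None = None,
    n_neighbors: int = 1,
    metric: str = "euclidean",
    seed: int = 0,
) -> PipelineBundle:
    """Fit imputation + scaling (+ optional SAE) + KNN on a training table."""
    medians = np.nanmedian(train.features, axis=0)
    x = train.impute_median(medians).features
    lo = x.min(axis=0)
    span = x.max(axis=0) - lo
    span = np.where(span == 0, 1.0, span)
    x_scaled = (x - lo) / span
    model = None
    if sae_config is not None:
        cfg = dataclasses.replace(sae_config, seed=seed)
        model = sae_mod.stack_train(x_scaled, cfg, labels=train.labels, scale=False)
    config_blob = json.dumps(
        {
            "sae": None if sae_config is None else dataclasses.asdict(sae_config),
            "n_neighbors": n_neighbors,
            "metric": metric,
            "seed": seed,
        },
        sort_keys=True,
        default=str,
    )
    provenance = {
        "seed": seed,
        "config_hash": hashlib.sha256(config_blob.encode()).hexdigest()[:12],
        "n_train_rows": train.n_rows,
    }
    return PipelineBundle(
        feature_names=train.feature_names,
        scaler_min=lo,
        scaler_range=span,
        medians=medians,
        train_features=x,
        train_labels=train.labels,
        n_neighbors=n_neighbors,
        metric=metric,
        sae=model,
        provenance=provenance,
    )


def save_bundle(bundle: PipelineBundle, path) -> None:
    """Serialise a bundle to one self-describing JSON file."""
    payload = {
        "format": BUNDLE_FORMAT,
        "version": BUNDLE_VERSION,
        "feature_names": list(bundle.feature_names),
        "scaler_min": bundle.scaler_min.tolist(),
        "scaler_range": bundle.scaler_range.tolist(),
        "medians": bundle.medians.tolist(),
        "train_features": bundle.train_features.tolist(),
        "train_labels": bundle.train_labels.tolist(),
        "n_neighbors": bundle.n_neighbors,
        "metric": bundle.metric,
        "sae": None if bundle.sae is None else bundle.sae.to_dict(),
        "provenance": bundle.provenance,
    }
    Path(path).write_text(json.dumps(payload))


def load_bundle(path) -> PipelineBundle:
    """Load a bundle saved by :func:`save_bundle` (validates the header)."""
    path = Path(path)
    payload = json.loads(path.read_text())
    if payload.get("format") != BUNDLE_FORMAT:
        raise ValueError(f"{path} is not a {BUNDLE_FORMAT} file")
    if payload.get("version") != BUNDLE_VERSION:
        raise ValueError(f"unsupported bundle version {payload.get('version')}")
    return PipelineBundle(
        feature_names=tuple(payload["feature_names"]),
        scaler_min=np.array(payload["scaler_min"]),
        scaler_range=np.array(payload["scaler_range"]),
        medians=np.array(payload["medians"]),
        train_features=np.array(payload["train_features"]),
        train_labels=np.array(payload["train_labels"], dtype=np.int64),
        n_neighbors=int(payload["n_neighbors"]),
        metric=payload["metric"],
        sae=None if payload["sae"] is None else SAEModel.from_dict(payload["sae"]),
        provenance=payload["provenance"],
    )
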