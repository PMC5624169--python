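"""Labeled feature-table container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["LabeledDataset"]


@dataclass(frozen=True)
class LabeledDataset:
    """Feature matrix with binary labels (1 = Parkinson's, 0 = healthy).

    ``subject_ids`` (optional) identify the speaker behind each row so that
    subject-level splits and leakage checks are possible on multi-recording
    cohorts.  NaN entries are allowed (missing features awaiting imputation);
    :meth:`impute_median` fills them column-wise.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        features = np.asarray(self.features, dtype=np.float64)
        labels = np.asarray(self.labels)
        if features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if features.shape[0] != labels.shape[0]:
            raise ValueError(
                f"{features.shape[0]} feature rows but {labels.shape[0]} labels"
            )
        if features.shape[0] == 0:
            raise ValueError("dataset has zero rows")
        if features.shape[1] != len(self.feature_names):
            raise ValueError(
                f"{features.shape[1]} feature columns but {len(self.feature_names)} names"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1 (1 = PD)")
        labels = labels.astype(np.int64)
        if self.subject_ids is not None:
            ids = np.asarray(self.subject_ids)
            if ids.shape[0] != features.shape[0]:
                raise ValueError("subject_ids must align with rows")
            object.__setattr__(self, "subject_ids", ids)
        object.__setattr__(self, "features", features)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        indices = np.asarray(indices)
        return replace(
            self,
            features=self.features[indices],
            labels=self.labels[indices],
            subject_ids=None if self.subject_ids is None else self.subject_ids[indices],
        )

    def impute_median(self, medians: np.ndarray | None = None) -> "LabeledDataset":
        """Fill NaNs column-wise with ``medians`` (default: own nanmedians)."""
        if medians is None:
            medians = np.nanmedian(self.features, axis=0)
        filled = np.where(np.isnan(self.features), medians, self.features)
        return replace(self, features=filled)

    def to_frame(self, label_column: str = "status") -> pd.DataFrame:
        frame = pd.DataFrame(self.features, columns=list(self.feature_names))
        if self.subject_ids is not None:
            frame.insert(0, "subject_id", self.subject_ids)
        frame[label_column] = self.labels
        return frame
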