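"""Labelled sample populations produced by the ground-truth simulators.

A :class:`Dataset` bundles the feature matrix ``X`` (one row per sample),
the outcome vector ``y`` (class label or real), and per-column metadata
describing each feature as continuous, binary or categorical.  Datasets
are exchanged as plain CSV with an ``id`` column, one column per feature
and a final ``y`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_KINDS = ("continuous", "binary", "categorical")


@dataclass
class FeatureMeta:
    name: str
    kind: str  # continuous | binary | categorical
    levels: tuple | None = None  # fixed level set for categorical columns

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "categorical" and not self.levels:
            raise ValueError(f"categorical feature {self.name!r} needs levels")


@dataclass
class Dataset:
    """Feature matrix X (N x p), outcome y (length N) and metadata."""

    sample_ids: list
    X: pd.DataFrame
    y: np.ndarray
    feature_meta: list = field(default_factory=list)
    task: str = "classification"  # classification | regression
    model: str = ""
    classes: tuple | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y)
        if len(self.X) != len(self.y):
            raise ValueError("X and y disagree on sample count")
        if len(self.sample_ids) != len(self.y):
            raise ValueError("sample_ids and y disagree on sample count")
        if self.feature_meta:
            names = [m.name for m in self.feature_meta]
            if names != list(self.X.columns):
                raise ValueError("feature_meta does not match X columns")
        if self.task == "classification" and self.classes is None:
            self.classes = tuple(sorted(set(self.y.tolist())))

    @property
    def n_samples(self) -> int:
        return len(self.y)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def kinds(self) -> dict:
        return {m.name: m.kind for m in self.feature_meta}


def sample_ids(n: int, prefix: str = "s") -> list:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def write_dataset_csv(dataset: Dataset, path) -> None:
    frame = dataset.X.copy()
    frame.insert(0, "id", dataset.sample_ids)
    frame["y"] = dataset.y
    frame.to_csv(path, index=False)


def read_dataset_csv(path, feature_meta=None, task="classification",
                     model="") -> Dataset:
    frame = pd.read_csv(path)
    if "id" not in frame.columns or "y" not in frame.columns:
        raise ValueError("dataset CSV needs 'id' and 'y' columns")
    ids = frame["id"].astype(str).tolist()
    y = frame["y"].to_numpy()
    X = frame.drop(columns=["id", "y"])
    if feature_meta is None:
        feature_meta = [
            FeatureMeta(c, "binary" if set(np.unique(X[c])) <= {0, 1}
                        else "continuous")
            if np.issubdtype(X[c].dtype, np.number)
            else FeatureMeta(c, "categorical",
                             levels=tuple(sorted(X[c].astype(str).unique())))
            for c in X.columns
        ]
    return Dataset(ids, X, y, feature_meta, task=task, model=model)
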