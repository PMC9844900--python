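"""Labeled-dataset container shared by the transform, model and benchmark."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LabeledDataset"]


@dataclass
class LabeledDataset:
    """Feature points with categorical class labels.

    ``points`` may be a numeric array (the common case) or any sequence of
    opaque objects usable by a custom semimetric.  Original labels are mapped
    to class indices ``1..n`` by sorted order; ``c`` is the size of the
    smallest class, which bounds the neighbor counts of the latent transform.
    """

    points: np.ndarray | list
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if isinstance(self.points, np.ndarray) or (
            len(self.points) and np.ndim(self.points[0]) <= 1
            and isinstance(self.points[0], (np.ndarray, list, tuple, float, int, np.floating, np.integer))
        ):
            try:
                self.points = np.asarray(self.points, dtype=float)
                if self.points.ndim == 1:
                    self.points = self.points[:, np.newaxis]
            except (TypeError, ValueError):
                pass  # opaque objects stay a list
        self.labels = list(self.labels)
        if len(self.points) != len(self.labels):
            raise ValueError(
                f"points ({len(self.points)}) and labels ({len(self.labels)}) differ in length"
            )
        self.classes = sorted(set(self.labels))
        if len(self.classes) < 2:
            raise ValueError("a labeled dataset needs at least 2 classes")
        if len(self.points) < len(self.classes):
            raise ValueError("need at least as many points as classes")
        self._index_of = {lab: i + 1 for i, lab in enumerate(self.classes)}
        self.y = np.array([self._index_of[lab] for lab in self.labels], dtype=int)

    # -- basic quantities -------------------------------------------------
    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def class_counts(self) -> np.ndarray:
        """Member counts per class index 1..n."""
        return np.bincount(self.y, minlength=self.n_classes + 1)[1:]

    @property
    def min_class_size(self) -> int:
        """``c``: cardinality of the smallest class."""
        return int(self.class_counts.min())

    def class_index(self, label) -> int:
        """1-based class index of an original label (sorted order)."""
        return self._index_of[label]

    def decode(self, indices) -> list:
        """Map class indices 1..n back to original labels."""
        return [self.classes[i - 1] for i in np.atleast_1d(indices)]

    def members_of(self, class_idx: int) -> np.ndarray:
        """Positions (row indices) of the members of class ``class_idx``."""
        return np.flatnonzero(self.y == class_idx)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str) -> "LabeledDataset":
        """Build from a DataFrame with numeric feature columns and one label column."""
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found in {list(df.columns)}")
        features = df.drop(columns=[label_column])
        try:
            X = features.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric feature values: {exc}") from exc
        labels = [str(v) for v in df[label_column]]
        ds = cls(points=X, labels=labels)
        ds.feature_names = list(features.columns)
        return ds
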