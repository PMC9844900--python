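"""Delimited-text input/output and run configuration."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .backend import BackendSpec
from .data import LabeledDataset
from .transform import TransformConfig

__all__ = ["read_labeled_csv", "write_labeled_csv", "RunConfig"]

# 17 significant digits round-trip IEEE doubles exactly
FLOAT_FORMAT = "%.17g"


def read_labeled_csv(path, label_column: str) -> LabeledDataset:
    """Read a header CSV with numeric feature columns and one label column.

    Labels are read as strings and mapped to class indices 1..n in sorted
    order; row order is preserved.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={label_column: str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if label_column not in df.columns:
        raise ValueError(
            f"{path}: label column {label_column!r} not found "
            f"(columns: {list(df.columns)})"
        )
    features = df.drop(columns=[label_column])
    bad = [c for c in features.columns
           if not np.issubdtype(pd.to_numeric(features[c], errors="coerce").dtype,
                                np.number)
           or pd.to_numeric(features[c], errors="coerce").isna().any()]
    if bad:
        rows = sorted({int(i) + 2 for c in bad  # +2: header + 1-based
                       for i in features.index[pd.to_numeric(features[c],
                                                             errors="coerce").isna()]})
        raise ValueError(
            f"{path}: non-numeric feature values in column(s) {bad}, "
            f"file row(s) {rows[:10]}"
        )
    return LabeledDataset.from_dataframe(df, label_column)


def write_labeled_csv(path, dataset: LabeledDataset, label_column: str = "label") -> None:
    """Write a LabeledDataset back to CSV (inverse of :func:`read_labeled_csv`)."""
    X = np.asarray(dataset.points, dtype=float)
    names = getattr(dataset, "feature_names", None) or \
        [f"x{i + 1}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df[label_column] = dataset.labels
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


class RunConfig:
    """YAML-backed run configuration for the command-line interface."""

    def __init__(self, raw: dict):
        self.raw = raw
        self.label_column = raw.get("label_column", "label")
        t = raw.get("transform", {})
        if "gamma" in t:
            self.transform = TransformConfig.from_gamma(
                t["gamma"], t.get("k_alpha", 1), t.get("k_beta", 1),
                t.get("semimetric", "euclidean"))
        else:
            self.transform = TransformConfig(
                alpha=t.get("alpha", 0.0), beta=t.get("beta", 1.0),
                k_alpha=t.get("k_alpha", 1), k_beta=t.get("k_beta", 1),
                semimetric=t.get("semimetric", "euclidean"))
        self.backend = BackendSpec.from_dict(raw.get("backend", {}))
        self.mc_samples = int(raw.get("mc_samples", 10_000))
        self.mc_seed = int(raw.get("mc_seed", 0))
        self.benchmark = raw.get("benchmark", {})

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: configuration must be a mapping")
        return cls(raw)
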