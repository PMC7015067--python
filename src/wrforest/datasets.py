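"""Tabular binary-classification containers and CSV I/O.

The whole package operates on a plain numeric feature matrix with a binary
{0, 1} label vector — the shape of data produced by upstream feature
extraction from clinical monitoring signals, but nothing here is specific
to that origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TrainingSet"]


@dataclass
class TrainingSet:
    """A feature matrix with a binary label vector.

    Parameters
    ----------
    features : ndarray of shape (n, n_features)
        Numeric predictors; no missing values.
    labels : ndarray of shape (n,)
        Class labels in {0, 1}; 1 is the positive (event/true-alarm) class.
    feature_names : list of str
        One name per feature column.
    label_name : str
        Name of the label column used on CSV round-trips.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    label_name: str = "label"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels length must match the number of rows")
        if self.features.shape[0] < 2:
            raise ValueError("need at least two observations")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain missing or non-finite values")
        uniq = np.unique(self.labels)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("labels must take values in {0, 1}")
        self.labels = self.labels.astype(np.int64)
        if not self.feature_names:
            self.feature_names = [f"f{k + 1}" for k in range(self.features.shape[1])]
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length must match feature columns")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def has_both_classes(self) -> bool:
        return bool(self.labels.min() == 0 and self.labels.max() == 1)

    def subset(self, rows: np.ndarray) -> "TrainingSet":
        """Row-subset view (copies), preserving names."""
        return TrainingSet(
            self.features[rows],
            self.labels[rows],
            list(self.feature_names),
            self.label_name,
        )

    @classmethod
    def from_csv(
        cls,
        path,
        label_col: str = "label",
        positive_label: str | int | None = None,
    ) -> "TrainingSet":
        """Load from a headered CSV.

        Labels may be 0/1 integers or any two string levels; with string
        levels ``positive_label`` selects the level mapped to 1 (default:
        the lexicographically larger level).
        """
        df = pd.read_csv(path)
        if label_col not in df.columns:
            raise ValueError(f"label column {label_col!r} not found in {path}")
        y_raw = df[label_col]
        x = df.drop(columns=[label_col])
        levels = pd.unique(y_raw)
        if set(levels) <= {0, 1}:
            y = y_raw.to_numpy(dtype=np.int64)
        else:
            if len(levels) != 2:
                raise ValueError(
                    f"label column {label_col!r} must be binary, got {len(levels)} levels"
                )
            if positive_label is None:
                positive_label = sorted(map(str, levels))[-1]
            y = (y_raw.astype(str) == str(positive_label)).astype(np.int64).to_numpy()
        return cls(x.to_numpy(dtype=float), y, list(x.columns), label_col)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df[self.label_name] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
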