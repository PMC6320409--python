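"""Named feature columns x instance rows, shared by the quality and detection pipelines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError


@dataclass
class FeatureMatrix:
    """Instances x features with a dichotomous class label and subject id per row."""

    feature_names: list[str]
    X: np.ndarray
    labels: np.ndarray
    groups: np.ndarray
    row_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.X.ndim != 2:
            raise ConfigError("X must be 2-d (instances x features)")
        n, k = self.X.shape
        if len(self.feature_names) != k:
            raise ConfigError(f"{len(self.feature_names)} names for {k} columns")
        if len(set(self.feature_names)) != k:
            raise ConfigError("feature names must be unique")
        if len(self.labels) != n or len(self.groups) != n:
            raise ConfigError("labels/groups length must match row count")
        if not np.all(np.isfinite(self.X)):
            raise ConfigError("feature matrix contains non-finite values")
        if not self.row_ids:
            self.row_ids = [str(i) for i in range(n)]

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def class_order(self) -> list:
        return sorted({str(l) for l in self.labels})

    def require_two_classes(self) -> None:
        """Dichotomous-task guard used by selection and cross-validation."""
        if len(self.class_order()) < 2:
            raise ConfigError("need at least 2 distinct class labels")

    def encoded_labels(self) -> np.ndarray:
        """Class encoded {0, 1} in sorted label order."""
        order = self.class_order()
        return np.asarray([order.index(str(l)) for l in self.labels], dtype=float)

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.feature_names.index(name)]

    def select_features(self, names: list[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            feature_names=list(names),
            X=self.X[:, idx],
            labels=self.labels.copy(),
            groups=self.groups.copy(),
            row_ids=list(self.row_ids),
        )

    def take_rows(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx, dtype=int)
        return FeatureMatrix(
            feature_names=list(self.feature_names),
            X=self.X[idx],
            labels=self.labels[idx],
            groups=self.groups[idx],
            row_ids=[self.row_ids[i] for i in idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "row_id", self.row_ids)
        df.insert(1, "subject_id", self.groups)
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_arff(self, path, relation: str = "transferkit") -> None:
        """Minimal ARFF export (numeric attributes + nominal class)."""
        classes = ",".join(str(c) for c in self.class_order())
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"@RELATION {relation}\n\n")
            for name in self.feature_names:
                fh.write(f"@ATTRIBUTE {name} NUMERIC\n")
            fh.write(f"@ATTRIBUTE class {{{classes}}}\n\n@DATA\n")
            for row, lab in zip(self.X, self.labels):
                vals = ",".join(f"{v:.10g}" for v in row)
                fh.write(f"{vals},{lab}\n")
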