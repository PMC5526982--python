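"""The sample-by-feature container shared across the package.

A :class:`FeatureMatrix` is a plain N×P float array with a label per row,
optional feature names, and optional subject identifiers (several scans of
one subject share an identifier; the cross-validation machinery groups on
them to avoid leakage between repeated measurements).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError, ShapeError

__all__ = ["FeatureMatrix"]


@dataclass
class FeatureMatrix:
    """N×P numeric feature table with per-sample class labels.

    Parameters
    ----------
    values
        Real matrix, one row per sample. Units may differ per column
        (e.g. mm^3 volumes next to mm thicknesses); downstream fitting
        standardizes internally.
    labels
        Length-N vector of class identifiers (any hashable scalar type).
    feature_names
        Optional length-P identifiers.
    subjects
        Optional length-N subject identifiers for grouped CV / splitting.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str] | None = None
    subjects: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ShapeError(f"values must be 2-D, got shape {self.values.shape}")
        if self.labels.shape != (self.values.shape[0],):
            raise ShapeError(
                f"labels length {self.labels.shape} does not match "
                f"{self.values.shape[0]} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            r, c = bad[0]
            raise ParameterError(
                f"{len(bad)} non-finite entries; first at row {r}, column {c}"
            )
        if self.feature_names is not None and len(self.feature_names) != self.values.shape[1]:
            raise ShapeError("feature_names length does not match feature count")
        if self.subjects is not None:
            self.subjects = np.asarray(self.subjects)
            if self.subjects.shape != (self.values.shape[0],):
                raise ShapeError("subjects length does not match sample count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Sorted unique class identifiers."""
        return np.unique(self.labels)

    @property
    def n_classes(self) -> int:
        return self.classes.size

    def require_supervised(self) -> None:
        """Raise unless at least two classes are present."""
        from .exceptions import DegenerateLabelsError

        if self.n_classes < 2:
            raise DegenerateLabelsError(
                "supervised operations need at least two classes, got "
                f"{self.n_classes}"
            )

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        """Row subset preserving metadata."""
        return FeatureMatrix(
            self.values[idx],
            self.labels[idx],
            self.feature_names,
            None if self.subjects is None else self.subjects[idx],
        )
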