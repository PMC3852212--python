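"""In-memory containers for expression matrices and patient labels.

An :class:`ExpressionDataset` is a dense patients x features matrix with
explicit, ordered patient and feature identifiers; it is the common currency
between the graph-construction modules. A :class:`LabelVector` holds one value
per patient in {-1, 0, +1}, where 0 marks an unlabeled patient whose outcome
the semi-supervised solver is asked to score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError

__all__ = ["ExpressionDataset", "LabelVector", "standardize_features"]


@dataclass(frozen=True)
class ExpressionDataset:
    """A patients x features real-valued matrix with ID lists.

    Parameters
    ----------
    values
        2-D float array of shape ``(n_patients, n_features)``; no NaN/inf.
    patient_ids
        Ordered, unique patient identifiers (rows).
    feature_ids
        Ordered, unique feature identifiers (columns); genes or miRNAs.
    """

    values: np.ndarray
    patient_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "patient_ids", tuple(str(p) for p in self.patient_ids))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        if values.ndim != 2:
            raise ConfigurationError("values must be a 2-D matrix")
        if values.shape != (len(self.patient_ids), len(self.feature_ids)):
            raise ConfigurationError(
                f"values shape {values.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.feature_ids)} features"
            )
        if not np.all(np.isfinite(values)):
            raise ConfigurationError("values contains non-finite entries")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ConfigurationError("patient_ids are not unique")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ConfigurationError("feature_ids are not unique")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def subset_features(self, feature_ids: list[str] | tuple[str, ...]) -> "ExpressionDataset":
        """Restrict to the given features, in the given order."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise ConfigurationError(f"unknown feature ids: {missing[:5]}")
        cols = [index[f] for f in feature_ids]
        return ExpressionDataset(self.values[:, cols], self.patient_ids, tuple(feature_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.patient_ids), columns=list(self.feature_ids))

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "patient_id"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path) -> "ExpressionDataset":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), tuple(df.index.astype(str)), tuple(df.columns.astype(str)))


@dataclass(frozen=True)
class LabelVector:
    """Per-patient label in {-1, 0, +1}; 0 = unlabeled."""

    values: np.ndarray
    patient_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "patient_ids", tuple(str(p) for p in self.patient_ids))
        if values.ndim != 1 or values.shape[0] != len(self.patient_ids):
            raise ConfigurationError("labels length does not match patient_ids")
        if not np.isin(values, (-1, 0, 1)).all():
            raise ConfigurationError("labels must take values in {-1, 0, +1}")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.values != 0

    def masked(self, keep: np.ndarray) -> "LabelVector":
        """Zero out (unlabel) every patient where ``keep`` is False."""
        keep = np.asarray(keep, dtype=bool)
        out = np.where(keep, self.values, 0)
        return LabelVector(out, self.patient_ids)

    def write_tsv(self, path) -> None:
        pd.DataFrame({"patient_id": list(self.patient_ids), "label": self.values}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read_tsv(cls, path) -> "LabelVector":
        df = pd.read_csv(path, sep="\t")
        return cls(df["label"].to_numpy(dtype=int), tuple(df["patient_id"].astype(str)))


def check_same_patients(a: ExpressionDataset, b: ExpressionDataset | LabelVector) -> None:
    if a.patient_ids != b.patient_ids:
        raise AlignmentError("patient ID lists differ between datasets")


def standardize_features(values: np.ndarray) -> np.ndarray:
    """Per-feature zero-mean, unit-variance scaling over patients.

    Constant features (zero variance) are mapped to all-zero columns rather
    than dividing by zero, so they contribute nothing to distances.
    """
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (values - mean) / sd
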