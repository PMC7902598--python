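"""Core in-memory containers shared by every pipeline stage.

A :class:`FeatureTable` is a thin wrapper around a samples-by-features
:class:`pandas.DataFrame` (index = sample identifiers, columns = feature
names) carrying a *modality* tag — ``"clinical"`` or the name of an omics
layer.  A decision vector is a plain :class:`pandas.Series` of 0/1 labels
aligned to the same sample identifiers (1 = positive class, e.g. deceased).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "as_decision_vector", "align_tables"]


@dataclass
class FeatureTable:
    """Samples × features numeric matrix with sample IDs and a modality tag."""

    data: pd.DataFrame
    modality: str = "clinical"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("FeatureTable.data must be a pandas DataFrame")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature names: {dupes}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def select(self, features: Sequence[str]) -> "FeatureTable":
        missing = [f for f in features if f not in self.data.columns]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        return FeatureTable(self.data.loc[:, list(features)], self.modality)

    def drop(self, features: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.data.drop(columns=list(features)), self.modality)

    def restrict(self, sample_ids: Sequence) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(sample_ids)], self.modality)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.modality)

    def __eq__(self, other: object) -> bool:  # value equality, for determinism tests
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.modality == other.modality and self.data.equals(other.data)


def as_decision_vector(y, index=None) -> pd.Series:
    """Validate and coerce labels into a binary 0/1 decision vector."""
    s = pd.Series(y, index=index) if index is not None else pd.Series(y)
    levels = sorted(pd.unique(s.dropna()))
    if len(levels) != 2 or set(levels) != {0, 1}:
        raise ValueError(f"decision vector must be binary 0/1; found levels {levels}")
    if s.isna().any():
        raise ValueError("decision vector contains missing values")
    if s.index.has_duplicates:
        raise ValueError("duplicate sample IDs in decision vector")
    return s.astype(np.int8)


def align_tables(
    tables: Iterable[FeatureTable], y: pd.Series
) -> tuple[list[FeatureTable], pd.Series, pd.Index]:
    """Restrict tables and decision vector to the common sample-ID intersection.

    Order follows the first table's sample order.  Returns the aligned tables,
    aligned decision vector and the intersection index.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to align")
    common = tables[0].sample_ids
    for t in tables[1:]:
        common = common[common.isin(t.sample_ids)]
    common = common[common.isin(y.index)]
    if len(common) == 0:
        raise ValueError("empty sample-ID intersection across tables")
    aligned = [t.restrict(common) for t in tables]
    return aligned, y.loc[common], common
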