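"""Delimited-table readers, sample-ID alignment and provenance capture.

All tables are delimited text (comma or tab, auto-detected) with a header
row and the sample ID in the first column.  A :class:`DataBundle` holds
the clinical table, the named omics tables and the decision vector, all
restricted to the common sample-ID intersection in identical order — the
"complete records" policy — plus provenance (file hashes, seeds, configs).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .tables import FeatureTable, as_decision_vector, align_tables

__all__ = ["DataBundle", "read_table", "load_bundle"]


@dataclass
class DataBundle:
    clinical: FeatureTable
    omics: dict[str, FeatureTable]
    y: pd.Series
    sample_ids: pd.Index
    provenance: dict = field(default_factory=dict)
    dropped: dict[str, int] = field(default_factory=dict)


def _sniff_sep(path: Path) -> str:
    head = path.open().readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_table(path: str | Path, modality: str) -> FeatureTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    return FeatureTable(df, modality)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def load_bundle(
    clinical_path: str | Path,
    omics_paths: dict[str, str | Path],
    decision_path: str | Path,
    decision_column: str = "decision",
) -> DataBundle:
    """Load and intersection-align a multi-modal bundle from delimited files.

    Raises on an empty intersection, a non-binary decision column or
    duplicate sample IDs; reports per-table dropped sample counts.
    """
    clinical = read_table(clinical_path, "clinical")
    omics = {name: read_table(p, name) for name, p in omics_paths.items()}
    dec_path = Path(decision_path)
    dec = pd.read_csv(dec_path, sep=_sniff_sep(dec_path), index_col=0)
    if decision_column not in dec.columns:
        raise KeyError(f"decision column {decision_column!r} not in {dec_path.name}")
    col = dec[decision_column]
    levels = sorted(col.dropna().unique().tolist())
    if len(levels) != 2:
        raise ValueError(f"decision column must be binary; found levels {levels}")
    if set(levels) != {0, 1}:  # map the two observed levels onto 0/1, sorted order
        col = col.map({levels[0]: 0, levels[1]: 1})
    y = as_decision_vector(col)

    tables = [clinical, *omics.values()]
    aligned, y_aligned, common = align_tables(tables, y)
    dropped = {
        t.modality: t.n_samples - len(common) for t in tables
    }
    provenance = {
        "files": {
            "clinical": _file_hash(Path(clinical_path)),
            "decision": _file_hash(dec_path),
            **{name: _file_hash(Path(p)) for name, p in omics_paths.items()},
        },
        "decision_levels": levels,
    }
    return DataBundle(
        clinical=aligned[0],
        omics={t.modality: t for t in aligned[1:]},
        y=y_aligned,
        sample_ids=common,
        provenance=provenance,
        dropped=dropped,
    )
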