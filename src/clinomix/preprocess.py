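"""Missing-value imputation, log transformation and the signal prefilter.

Molecular tables are cleaned before feature selection: per-feature mean or
median imputation, optional log2 transform, and a two-criterion prefilter
that removes low-intensity and low-variation features.  The intensity
threshold ``T`` is a configurable quantile (default: first quartile) of the
distribution of per-feature maxima; a feature is kept only if at least a
minimum fraction of samples (default 10%) exceed ``T`` *and* its robust
coefficient of variation exceeds a floor (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .tables import FeatureTable

__all__ = ["PrefilterConfig", "impute_missing", "log2_transform", "intensity_variation_filter"]


@dataclass(frozen=True)
class PrefilterConfig:
    intensity_quantile: float = 0.25
    min_fraction_above: float = 0.10
    robust_cv_min: float = 0.05
    log2: bool = False
    imputation: Literal["mean", "median"] = "mean"

    def __post_init__(self) -> None:
        if not 0.0 <= self.intensity_quantile <= 1.0:
            raise ValueError("intensity_quantile must be in [0, 1]")
        if not 0.0 <= self.min_fraction_above <= 1.0:
            raise ValueError("min_fraction_above must be in [0, 1]")
        if self.robust_cv_min < 0:
            raise ValueError("robust_cv_min must be >= 0")


def impute_missing(table: FeatureTable, strategy: Literal["mean", "median"] = "mean") -> FeatureTable:
    """Replace missing entries by the per-feature mean or median of observed values."""
    if strategy not in ("mean", "median"):
        raise ValueError(f"unknown imputation strategy: {strategy!r}")
    df = table.data
    all_missing = df.columns[df.isna().all(axis=0)]
    if len(all_missing) > 0:
        raise ValueError(f"features entirely missing, cannot impute: {list(all_missing)}")
    if not df.isna().any().any():
        return table.copy()
    fill = df.mean(axis=0) if strategy == "mean" else df.median(axis=0)
    return FeatureTable(df.fillna(fill), table.modality)


def log2_transform(table: FeatureTable) -> FeatureTable:
    """Log2-transform all values; values <= 0 are an error."""
    vals = table.data.to_numpy(dtype=float)
    if np.nanmin(vals) <= 0:
        bad = table.data.columns[(table.data <= 0).any(axis=0)].tolist()
        raise ValueError(f"log2 transform requires strictly positive values; offending features: {bad[:10]}")
    return FeatureTable(np.log2(table.data), table.modality)


def robust_cv(values: np.ndarray) -> float:
    """Robust coefficient of variation: IQR / (1.349 · |median|).

    A feature with zero IQR has no variation and gets 0 regardless of its
    median; a variable feature centred at median 0 gets +inf (never dropped
    by the variation criterion).
    """
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    if iqr == 0:
        return 0.0
    if med == 0:
        return np.inf
    return iqr / (1.349 * abs(med))


def intensity_variation_filter(
    table: FeatureTable,
    config: PrefilterConfig = PrefilterConfig(),
    intensity_threshold: float | None = None,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop low-intensity and low-variation features.

    Returns the filtered table (feature order preserved, values untouched)
    and a report DataFrame with columns (feature, reason) for every dropped
    feature; the threshold actually used is stored in
    ``report.attrs["intensity_threshold"]``.  When ``config.log2`` is set,
    the transform is applied first and both criteria are evaluated on the
    log scale.

    The intensity threshold is a property of the full cohort: by default it
    is the configured quantile of the per-feature maxima of ``table``, but
    it can be passed explicitly (``intensity_threshold``), e.g. to re-apply
    a previously computed filter — with a held threshold the filter is
    idempotent, whereas recomputing it on an already filtered table would
    raise it and drop further features.

    The quantile uses NumPy's linear-interpolation convention; at small
    feature counts the kept set can depend on this choice.
    """
    if table.n_features == 0:
        raise ValueError("empty table")
    if table.data.isna().any().any():
        raise ValueError("prefilter requires imputed (complete) data")
    if config.log2:
        table = log2_transform(table)
    X = table.values()
    maxima = X.max(axis=0)
    if intensity_threshold is None:
        threshold = float(np.quantile(maxima, config.intensity_quantile))
    else:
        threshold = float(intensity_threshold)
    frac_above = (X > threshold).mean(axis=0)
    cvs = np.array([robust_cv(X[:, j]) for j in range(X.shape[1])])

    keep = (frac_above >= config.min_fraction_above) & (cvs > config.robust_cv_min)
    reasons = []
    for j, name in enumerate(table.feature_names):
        if keep[j]:
            continue
        why = []
        if frac_above[j] < config.min_fraction_above:
            why.append("low_intensity")
        if cvs[j] <= config.robust_cv_min:
            why.append("low_variation")
        reasons.append((name, "+".join(why)))
    report = pd.DataFrame(reasons, columns=["feature", "reason"])
    report.attrs["intensity_threshold"] = threshold
    if not keep.any():
        raise ValueError(
            f"all {table.n_features} features dropped by the prefilter "
            f"(threshold={threshold:.4g}); reasons: {report['reason'].value_counts().to_dict()}"
        )
    kept = [f for f, k in zip(table.feature_names, keep) if k]
    return table.select(kept), report
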