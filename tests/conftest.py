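import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from clinomix import (
    CohortConfig,
    ClinicalFeatureSpec,
    OmicsLayerSpec,
    FeatureTable,
    generate_cohort,
)
from clinomix.synthetic import null_cohort_config, signal_cohort_config


def make_table(matrix, names=None, modality="clinical", ids=None) -> FeatureTable:
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    names = names or [f"f{j}" for j in range(p)]
    ids = ids or [f"S{i:04d}" for i in range(n)]
    return FeatureTable(pd.DataFrame(matrix, index=ids, columns=names), modality)


@pytest.fixture(scope="session")
def small_signal_cohort():
    """n=300 cohort with strong clinical + weak-omics GE layer (300 features)."""
    cfg = signal_cohort_config(n_samples=300, seed=42, n_omics_features=300)
    clinical, omics, y, truth = generate_cohort(cfg)
    return clinical, {"GE": omics[0]}, y, truth


@pytest.fixture(scope="session")
def null_cohort():
    """n=300 cohort with zero effect sizes everywhere."""
    cfg = null_cohort_config(n_samples=300, seed=7, n_omics_features=150)
    clinical, omics, y, truth = generate_cohort(cfg)
    return clinical, {"GE": omics[0]}, y, truth
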