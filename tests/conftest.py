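"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cardiosc import CountMatrix, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Desk-scale cohort: 6 donor + 4 DCM samples, 80 cells each."""
    return SimulationConfig(
        n_samples_donor=6,
        n_samples_dcm=4,
        cells_per_sample=80,
        n_genes=400,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size cohort at generator defaults (shared, read-only)."""
    return simulate_dataset(SimulationConfig(seed=7))


@pytest.fixture()
def toy_counts() -> CountMatrix:
    """Hand-written 3 genes x 4 cells matrix."""
    values = np.array(
        [
            [3, 0, 1, 2],
            [0, 0, 4, 0],
            [5, 1, 0, 1],
        ]
    )
    return CountMatrix(sp.csr_matrix(values), ["g1", "g2", "g3"], list("abcd"))


@pytest.fixture()
def toy_annotation() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s2", "s2"],
            "modality": ["cell"] * 4,
            "condition": ["donor", "donor", "DCM", "DCM"],
            "sex": ["male", "male", "female", "female"],
            "age": [50.0, 50.0, 60.0, 60.0],
            "cluster": ["T0", "T1", "T0", "T1"],
            "n_umi": [8, 1, 5, 3],
            "pct_mito": [0.0, 0.0, 0.0, 0.0],
            "doublet": [False] * 4,
        },
        index=list("abcd"),
    )
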