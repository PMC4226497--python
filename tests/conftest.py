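import numpy as np
import pytest

from mccpk import ScanSimConfig, simulate_scan_dataset
from mccpk.estimation import normalize_counts


@pytest.fixture(scope="session")
def ncf_dataset():
    """NCF study-condition dataset: n=9, Poisson counting noise, no
    inter-subject spread (group truth is exactly the group mean)."""
    cfg = ScanSimConfig.for_group("NCF", inter_subject_cv=0.0, seed=101)
    dataset, truth = simulate_scan_dataset(cfg)
    return dataset, truth


@pytest.fixture(scope="session")
def ncf_subjects(ncf_dataset):
    dataset, _ = ncf_dataset
    return normalize_counts(dataset)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
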