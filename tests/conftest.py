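import numpy as np
import pandas as pd
import pytest

from blankgate.io import CpTable, Metadata, OtuTable
from blankgate.simulate import SyntheticConfig, generate_dataset, study_like_config


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic study under the default conditions."""
    return generate_dataset(SyntheticConfig(), seed=7)


@pytest.fixture(scope="session")
def study_dataset():
    """Synthetic study with coverage enforcement: exactly 875 distinct
    OTUs, 156 observed in blanks."""
    return generate_dataset(study_like_config(), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture()
def small_counts_table():
    data = pd.DataFrame(
        [[5, 0, 3, 2], [0, 7, 0, 1], [4, 4, 4, 0]],
        index=["S1", "S2", "S3"], columns=["a", "b", "c", "d"])
    return OtuTable(data, unit="counts")


@pytest.fixture()
def tiny_metadata():
    return Metadata.from_records([
        {"sample_id": "S1", "volume_ml": 1000, "is_blank": False},
        {"sample_id": "S2", "volume_ml": 500, "is_blank": False},
        {"sample_id": "S3", "volume_ml": 100, "is_blank": False},
        {"sample_id": "B1", "volume_ml": 0, "is_blank": True,
         "blank_type": "filtered-water"},
    ])


def random_counts_table(rng, n_samples=6, n_otus=10, max_count=50,
                        with_blanks=0):
    """Random counts table (+ metadata when with_blanks > 0)."""
    counts = rng.integers(0, max_count, size=(n_samples, n_otus))
    # guarantee no all-zero rows
    for i in range(n_samples):
        if counts[i].sum() == 0:
            counts[i, rng.integers(n_otus)] = 1
    ids = [f"S{i}" for i in range(n_samples)]
    table = OtuTable(pd.DataFrame(counts, index=ids,
                                  columns=[f"O{j}" for j in range(n_otus)]),
                     unit="counts")
    if not with_blanks:
        return table
    records = []
    for i, sid in enumerate(ids):
        is_blank = i < with_blanks
        records.append({"sample_id": sid, "volume_ml": 0 if is_blank else 500,
                        "is_blank": is_blank,
                        "blank_type": "unused-filter" if is_blank else None})
    return table, Metadata.from_records(records)
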