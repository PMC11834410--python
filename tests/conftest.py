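import numpy as np
import pandas as pd
import pytest

from hostlink import io_formats
from hostlink import synthetic_data as sd

TINY_CONFIG = dict(
    n_taxa=40,
    n_timepoints=3,
    apples_per_timepoint=5,
    worms_per_apple_range=(1, 3),
    sequencing_depth_substrate=3000,
    sequencing_depth_host=1000,
    n_metabolites=8,
    metabolite_sparsity=0.1,
    presence_intercept=2.0,
    presence_ph_coeff=0.0,
    seed=11,
)


@pytest.fixture(scope="session")
def tiny_dataset() -> sd.SimulatedDataset:
    """One small simulated dataset shared across read-only tests."""
    return sd.generate_dataset(sd.SyntheticConfig(**TINY_CONFIG))


@pytest.fixture()
def toy_tree():
    """The three-leaf caterpillar used by the hand-derived metric examples."""
    return io_formats.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture()
def toy_counts():
    return pd.DataFrame(
        [[5, 3, 0], [1, 0, 4], [2, 2, 2]],
        index=["S1", "S2", "S3"],
        columns=["A", "B", "C"],
    )


def worm_ids(dataset: sd.SimulatedDataset) -> list[str]:
    meta = dataset.metadata
    return [s for s in dataset.counts.index if meta.at[s, "environment"] == "worm"]


def apple_ids(dataset: sd.SimulatedDataset) -> list[str]:
    meta = dataset.metadata
    return [s for s in dataset.counts.index if meta.at[s, "environment"] == "apple"]
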