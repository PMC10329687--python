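import dataclasses

import numpy as np
import pandas as pd
import pytest

from phylogeostrat import SimulationParams, simulate_dataset
from phylogeostrat.phylo import CodonAlignment


SMALL_PARAMS = SimulationParams(
    n_regions=3,
    samples_per_region=4,
    n_genes_neutral=4,
    n_genes_selected=4,
    gene_length=60,
    cities_per_region=3,
    seed=11,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A scaled-down synthetic dataset shared by fast unit tests."""
    return simulate_dataset(SMALL_PARAMS)


@pytest.fixture
def small_params():
    return SMALL_PARAMS


@pytest.fixture
def toy_meta():
    """Metadata for hand-built tip-filter scenarios."""

    def build(rows):
        return pd.DataFrame(
            rows, columns=["tip_id", "sample_id", "city", "region", "dedup_score"]
        )

    return build


@pytest.fixture
def aln_factory():
    def build(mapping):
        return CodonAlignment.from_dict(mapping)

    return build


def euclidean_dm(points):
    """Labeled Euclidean distance matrix from a list of coordinate tuples."""
    from skbio import DistanceMatrix

    x = np.atleast_2d(np.asarray(points, dtype=float))
    if x.ndim == 2 and x.shape[1] == 1:
        x = x.reshape(-1, 1)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(d, ids=[f"t{i}" for i in range(len(points))])
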