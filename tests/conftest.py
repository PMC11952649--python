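"""Shared fixtures: small synthetic datasets built at test time."""

import numpy as np
import pytest

from celldiffuse.core_io import CellTable, RunConfig, SpotExpression
from celldiffuse.simulate import (
    generate_positions,
    make_spots,
    sample_counts_truth,
    sample_programs,
)


@pytest.fixture(scope="session")
def small_truth():
    """Layered benchmark at reduced size: 900 cells, 80 genes."""
    cells = generate_positions(n_cells=900, layout="layers", seed=7)
    lam = sample_programs(n_genes=80, markers_per_type=(28, 28, 24), seed=8)
    return sample_counts_truth(cells, lam, seed=9)


@pytest.fixture(scope="session")
def small_spots(small_truth):
    return make_spots(small_truth, diameter=100.0, pitch=100.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def tiny_spots():
    """Four spots on a line, three genes, fully hand-specified."""
    return SpotExpression(
        spot_ids=np.array(["s0", "s1", "s2", "s3"]),
        coords=np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0], [30.0, 0.0]]),
        diameter=8.0,
        matrix=np.array(
            [
                [4.0, 0.0, 1.0],
                [2.0, 2.0, 2.0],
                [0.0, 5.0, 1.0],
                [1.0, 1.0, 6.0],
            ]
        ),
        gene_ids=np.array(["g0", "g1", "g2"]),
    )


@pytest.fixture()
def tiny_cells():
    return CellTable(
        cell_ids=np.array([f"c{i}" for i in range(6)]),
        centroids=np.array(
            [[0.0, 1.0], [1.0, 0.0], [10.0, 1.0], [11.0, 0.0], [20.0, 2.0], [29.0, 1.0]]
        ),
        morph_features=np.array(
            [[1.0, 0.2], [0.9, 0.1], [0.5, 0.5], [0.4, 0.6], [0.1, 0.9], [0.0, 1.0]]
        ),
    )


@pytest.fixture()
def default_config():
    return RunConfig()
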