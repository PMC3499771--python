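"""Shared fixtures: small graphs, random scans, and one session-scoped
default synthetic cohort with its degree maps (expensive, reused widely)."""

import numpy as np
import pytest

from fcmotif import (
    AdjacencyGraph,
    SubjectScan,
    SyntheticCohortConfig,
    VoxelGrid,
    build_correlation_matrix,
    degree_map,
    generate_cohort,
    threshold_graph,
)


def graph_from_array(A, mode="positive", tau=0.5, grid=None, voxel_linear_indices=None):
    A = np.asarray(A, dtype=bool)
    return AdjacencyGraph(A=A, mode=mode, tau=tau, grid=grid, voxel_linear_indices=voxel_linear_indices)


def random_graph(rng, n, density):
    """Random simple undirected graph as an AdjacencyGraph."""
    upper = rng.random((n, n)) < density
    A = np.triu(upper, k=1)
    A = A | A.T
    return graph_from_array(A)


def random_scan(rng, n_voxels=10, T=20, dims=(4, 4, 4)):
    """Random SubjectScan with n_voxels in-mask voxels on a small grid."""
    grid = VoxelGrid(dims=dims)
    mask = np.zeros(dims, dtype=bool)
    chosen = rng.choice(grid.n_voxels, size=n_voxels, replace=False)
    mask.reshape(-1)[chosen] = True
    X = rng.standard_normal((T, n_voxels))
    return SubjectScan(subject_id="rnd", grid=grid, anatomical_mask=mask, X=X)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """The default planted-effect synthetic cohort (seed 0): 40 + 40 subjects."""
    return generate_cohort(SyntheticCohortConfig(seed=0))


@pytest.fixture(scope="session")
def default_degree_maps(default_cohort):
    """Degree maps at tau = 0.70 (midpoint of the two coupling targets)."""
    return [
        degree_map(threshold_graph(build_correlation_matrix(s), 0.70, "positive"))
        for s in default_cohort
    ]


@pytest.fixture
def k4():
    """Complete graph on 4 nodes."""
    A = np.ones((4, 4), dtype=bool)
    np.fill_diagonal(A, False)
    return graph_from_array(A)


@pytest.fixture
def triangle():
    A = np.zeros((3, 3), dtype=bool)
    for i, j in [(0, 1), (1, 2), (0, 2)]:
        A[i, j] = A[j, i] = True
    return graph_from_array(A)
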