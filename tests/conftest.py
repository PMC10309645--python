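"""Shared fixtures: tiny hand meshes, a random Delaunay mesh, and
session-scoped desk-scale experiments reused by the heavier tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import Delaunay

import fmtrecon as fr


@pytest.fixture
def single_tet():
    return fr.TetMesh(
        nodes=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
        elements=[[0, 1, 2, 3]],
    )


@pytest.fixture
def two_tets():
    """Two tetrahedra sharing the face {1,2,3}; nodes 0 and 4 are not adjacent."""
    return fr.TetMesh(
        nodes=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]],
        elements=[[0, 1, 2, 3], [1, 2, 3, 4]],
    )


@pytest.fixture(scope="session")
def delaunay_mesh():
    """Random 200-node Delaunay tetrahedralization with its edge graph."""
    rng = np.random.default_rng(42)
    pts = rng.random((200, 3))
    mesh = fr.TetMesh(nodes=pts, elements=Delaunay(pts).simplices)
    return mesh, fr.edge_adjacency(mesh)


@pytest.fixture(scope="session")
def cube_25_2p5():
    return fr.generate_cube_mesh(25.0, 2.5)


def connected_sparse_signal(graph, rng, k=4, n=None):
    """Random k-sparse signal supported on an edge-connected node cluster."""
    n = n if n is not None else graph.n_nodes
    start = int(rng.integers(n))
    support = {start}
    while len(support) < k:
        support.add(int(rng.choice(sorted(fr.neighbor_set(graph, support)))))
    x = np.zeros(n)
    x[sorted(support)] = rng.uniform(0.5, 1.5, k)
    return x, support


@pytest.fixture(scope="session")
def single_target_experiment():
    """Noiseless single-target cube run: 25 mm cube, 2.5 mm inverse mesh,
    8 projections, centered 1.5 mm-radius target of yield 0.05."""
    targets = [fr.TargetSpec(center=(12.5, 12.5, 12.5), radius=1.5)]
    cfg = fr.ExperimentConfig(targets=targets, spacing_mm=2.5, noise_level=0.0,
                              seed=1, solvers=("nasols",))
    return fr.run_experiment(cfg), targets


@pytest.fixture(scope="session")
def double_target_experiment():
    """Noiseless double-target cube run at 4 mm edge-to-edge distance on a
    ~1.56 mm inverse mesh (solver runs are done per-test on its A, y)."""
    targets = [fr.TargetSpec(center=(9.5, 12.5, 12.5)),
               fr.TargetSpec(center=(15.5, 12.5, 12.5))]
    cfg = fr.ExperimentConfig(targets=targets, spacing_mm=25.0 / 16.0,
                              noise_level=0.0, seed=1, solvers=())
    return fr.run_experiment(cfg), targets
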