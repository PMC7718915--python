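import warnings

import numpy as np
import pytest

from laminmesh import meshgen, workbench
from laminmesh.simulator import SimulationConfig


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_mesh_geom():
    """A 48-node lambda=5.6 meshwork with relaxed filament lengths."""
    cfg = workbench.MeshConfig(n_nodes=48, rewire_iters=150_000,
                               coord_iters=120_000)
    return workbench.generate_mesh(5.6, cfg, seed=4)


@pytest.fixture(scope="session")
def small_bead_model(small_mesh_geom):
    return meshgen.discretize(small_mesh_geom)


@pytest.fixture
def fast_sim_config():
    return SimulationConfig(seed=4, steps_per_nm=500, dt=0.03,
                            max_displacement=140.0,
                            anneal=[(600.0, 600), (300.0, 900)])


@pytest.fixture(scope="session")
def planar_fixture():
    """Planar ground-truth meshwork + helper for edge-recall scoring."""
    geom = workbench.planar_mesh(seed=0)

    def recall(recovered, coords):
        from scipy.spatial.distance import cdist
        gt = geom.graph
        gtc = np.column_stack([geom.coords, np.zeros(gt.n_nodes)])
        D = cdist(gtc, coords)
        near = D.argmin(axis=1)
        edges = {tuple(e) for e in recovered.edges}
        ok = sum(
            1 for i, j in gt.edges
            if (min(near[i], near[j]), max(near[i], near[j])) in edges
            and D[i, near[i]] < 4 and D[j, near[j]] < 4)
        return ok / gt.n_edges

    return geom, recall
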