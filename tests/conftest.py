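import numpy as np
import pandas as pd
import pytest

from benthoval import synthdata as sd
from benthoval.meshfield import Mesh, SigmaScheme
from benthoval.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def small_mesh():
    mesh, scheme = sd.generate_mesh(extent=(5000.0, 5000.0), n_nodes=60, seed=11)
    return mesh, scheme


@pytest.fixture()
def square_mesh():
    """Hand-built 4-node mesh (two triangles) with non-contiguous node ids."""
    return Mesh(
        node_ids=np.array([2, 4, 9, 11]),
        x=np.array([0.0, 100.0, 0.0, 100.0]),
        y=np.array([0.0, 0.0, 100.0, 100.0]),
        h=np.array([50.0, 60.0, 70.0, 80.0]),
        elements=np.array([[2, 4, 9], [4, 11, 9]]),
    )


@pytest.fixture(scope="session")
def june_fields(small_mesh):
    """Sixteen June days of zero-bias fields (model equals truth, default noise)."""
    mesh, scheme = small_mesh
    tam = sd.generate_fields(
        mesh, scheme, start="2016-06-01", end="2016-06-17",
        bias=sd.BiasSchedule.constant(0.0), seed=21,
    )
    return mesh, scheme, tam


@pytest.fixture(scope="session")
def scenario():
    """Full two-period synthetic study at the default conditions.

    Two tagged individuals tracked from March 2016 to June 2017 over a model
    with a +0.53 degC warm bias through 2016 and a -0.045 degC residual bias
    after the new-year update.
    """
    return run_pipeline(RunConfig(seed=7, n_individuals=2))


def brute_force_nearest(mesh, point):
    """Independent exhaustive nearest-node scan (lowest id on ties)."""
    best_id, best_d = None, np.inf
    for nid, x, y in sorted(zip(mesh.node_ids, mesh.x, mesh.y)):
        d = (x - point[0]) ** 2 + (y - point[1]) ** 2
        if d < best_d:
            best_id, best_d = int(nid), d
    return best_id
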