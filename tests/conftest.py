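import numpy as np
import pandas as pd
import pytest

from morphotime.io import (
    SWC_AXON,
    SWC_DENDRITE,
    SWC_SOMA,
    FeatureTable,
    LayerGeometry,
    NeuronReconstruction,
)


def build_recon(nodes, cell_id="test", annotations=None):
    """Build a reconstruction from (id, parent, structure, x, y, z) tuples."""
    arr = list(nodes)
    return NeuronReconstruction(
        cell_id=cell_id,
        ids=np.array([n[0] for n in arr]),
        parents=np.array([n[1] for n in arr]),
        structure=np.array([n[2] for n in arr]),
        xyz=np.array([[n[3], n[4], n[5]] for n in arr], dtype=float),
        radius=np.full(len(arr), 0.5),
        annotations=annotations,
    )


@pytest.fixture
def geom():
    return LayerGeometry(pcl_top=0.0, ml_top=120.0)


@pytest.fixture
def three_node_recon():
    """Soma root, one dendrite child at distance 10, one axon child."""
    return build_recon([
        (1, -1, SWC_SOMA, 0.0, 50.0, 0.0),
        (2, 1, SWC_DENDRITE, 0.0, 60.0, 0.0),
        (3, 1, SWC_AXON, 8.0, 50.0, 0.0),
    ])


def random_compartment_tree(seed, n_nodes=200, step=2.0, compartment=SWC_AXON):
    """Random subdivided tree of one compartment hanging off a soma."""
    rng = np.random.default_rng(seed)
    nodes = [(1, -1, SWC_SOMA, 0.0, 50.0, 0.0)]
    pts = {1: np.array([0.0, 50.0, 0.0])}
    parents = [1]
    for i in range(2, n_nodes + 2):
        parent = int(rng.choice(parents[-30:])) if i > 2 else 1
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pt = pts[parent] + direction * rng.uniform(0.2, step)
        nodes.append((i, parent, compartment, *pt))
        pts[i] = pt
        parents.append(i)
    return build_recon(nodes)


def toy_table(seed=0, n=12, p=4, ids=None):
    rng = np.random.default_rng(seed)
    idx = pd.Index(ids if ids is not None
                   else [f"c{i:02d}" for i in range(n)], name="cell_id")
    X = pd.DataFrame(rng.normal(size=(n, p)), index=idx,
                     columns=[f"f{j}" for j in range(p)])
    return FeatureTable(X)


def two_blob_table(seed=0, n_a=10, n_b=10, gap=12.0, p=4):
    """Two well-separated Gaussian blobs; returns (table, labels)."""
    rng = np.random.default_rng(seed)
    Xa = rng.normal(0.0, 1.0, size=(n_a, p))
    Xb = rng.normal(gap, 1.0, size=(n_b, p))
    X = np.vstack([Xa, Xb])
    idx = pd.Index([f"c{i:02d}" for i in range(n_a + n_b)], name="cell_id")
    labels = pd.Series(["A"] * n_a + ["B"] * n_b, index=idx)
    return FeatureTable(pd.DataFrame(
        X, index=idx, columns=[f"f{j}" for j in range(p)])), labels
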