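import numpy as np
import pandas as pd
import pytest

import avec
from avec.dataset import ExpressionDataset
from avec.synthetic import ClusterProgram, SyntheticSpec


def make_dataset(counts, genes=None, cells=None, norm=None, **kw):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    cells = cells or [f"c{i}" for i in range(counts.shape[1])]
    return ExpressionDataset(counts=counts, genes=genes, cells=cells, norm=norm, **kw)


def norm_dataset(norm, genes=None, cells=None):
    """Dataset with an explicitly chosen normalized layer (counts are a
    nonzero placeholder so the container's invariants hold)."""
    norm = np.asarray(norm, dtype=float)
    counts = np.where(norm > 0, 1, 0).astype(int)
    return make_dataset(counts, genes=genes, cells=cells, norm=norm)


@pytest.fixture(scope="session")
def vec_data():
    """The eight-cluster arteriovenous study structure: 2000 genes x 800 cells,
    planted programs at log2FC 2, fixed seed."""
    return avec.generate_vec_dataset(avec.default_vec_spec(seed=1))


@pytest.fixture(scope="session")
def null_data():
    return avec.generate_null_dataset(avec.null_spec(n_genes=1000, n_cells=200, seed=3))


@pytest.fixture(scope="session")
def continuum_data():
    return avec.generate_vec_dataset(avec.continuum_spec(seed=4))


def refinement_spec(n_cells=300, flip=0.10, seed=6):
    """Two separable clusters with opposing marker programs (as in the real
    venous-plexus/arterial-plexus contrast) and planted label flips."""
    prog_a = {f"fa_{i}": 1.5 for i in range(25)}
    prog_b = {f"fb_{i}": 1.5 for i in range(25)}
    return SyntheticSpec(
        n_genes=500,
        n_cells=n_cells,
        cluster_profile=[
            ClusterProgram("A", 0.5, prog_a),
            ClusterProgram("B", 0.5, prog_b),
        ],
        flip_fraction=flip,
        seed=seed,
    )


@pytest.fixture(scope="session")
def refine_data():
    return avec.generate_vec_dataset(refinement_spec())


@pytest.fixture(scope="session")
def mc_vec_data():
    return avec.generate_mc_vec_pair(avec.mc_vec_spec(seed=5))


@pytest.fixture(scope="session")
def two_species_data():
    return avec.generate_two_species(avec.two_species_spec(seed=7))


def cluster_cells(truth, name, column="true_cluster"):
    return list(truth.cells.index[truth.cells[column] == name])
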