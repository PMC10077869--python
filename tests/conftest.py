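import numpy as np
import pytest

from fcgnn import GraphConfig, build_knn_graph
from fcgnn.gnn_models import prepare_graphs
from fcgnn.synthetic_data import SyntheticCohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_fc_matrix(rng, r):
    """A random symmetric zero-diagonal matrix with distinct |z| values."""
    z = rng.normal(scale=0.5, size=(r, r))
    z = (z + z.T) / 2
    np.fill_diagonal(z, 0.0)
    return z


@pytest.fixture
def small_cohort():
    """A small, clearly separable cohort for fast training tests:
    30 subjects per group, 24 regions."""
    spec = SyntheticCohortSpec(n_per_group=(30, 30), n_regions=24,
                               effect_size=1.5, noise_sd=0.2,
                               n_effect_edges=30, seed=42)
    cohort, truth = generate_cohort(spec, GraphConfig(k=5))
    return cohort, truth


@pytest.fixture
def small_prepped(small_cohort):
    cohort, _ = small_cohort
    return prepare_graphs(cohort.graphs), cohort.labels


@pytest.fixture
def tiny_graph(rng):
    """One random 8-node KNN connectome graph."""
    from fcgnn import FCMatrix

    z = random_fc_matrix(rng, 8)
    fc = FCMatrix(subject_id="t0", z=z)
    return build_knn_graph(fc, GraphConfig(k=2))
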