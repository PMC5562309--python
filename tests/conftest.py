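import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ribodereg as rd

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def abc_genes():
    return rd.GeneSet("abc", ("A", "B", "C"))


@pytest.fixture
def small_matrix(abc_genes):
    """3 genes x 4 samples, two normals and two tumors."""
    data = pd.DataFrame(
        {
            "N1": [10.0, 30.0, 60.0],
            "N2": [20.0, 30.0, 50.0],
            "T1": [40.0, 35.0, 25.0],
            "T2": [25.0, 25.0, 50.0],
        },
        index=abc_genes.index(),
    )
    groups = {"N1": "normal", "N2": "normal", "T1": "tumor", "T2": "tumor"}
    return rd.ExpressionMatrix(abc_genes, data, groups)


@pytest.fixture
def rel_small(small_matrix):
    return rd.relative_percent(small_matrix)


@pytest.fixture
def reference_small(rel_small):
    return rd.normal_reference(rel_small.subset_samples(["N1", "N2"]))


def make_reference(n_genes=77, sigma_frac=0.10, seed=0):
    """A plausible normal reference: log-spread means, proportional sigmas."""
    rng = np.random.default_rng(seed)
    gene_set = rd.GeneSet("ref", tuple(f"G{i:03d}" for i in range(n_genes)))
    mu = 10.0 ** rng.uniform(-2, 1, n_genes)
    mu = 100.0 * mu / mu.sum()
    sigma = sigma_frac * mu
    return rd.NormalReference(
        gene_set,
        pd.Series(mu, index=gene_set.index()),
        pd.Series(sigma, index=gene_set.index()),
        n_normals=1000,
    )


@pytest.fixture
def plausible_reference():
    return make_reference()
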