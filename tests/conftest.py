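import numpy as np
import pandas as pd
import pytest

from sigshift.data import ExpressionMatrix, SampleTable
from sigshift.synthetic import GeneratorSpec, make_compendium, make_study, make_two_group


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples, two groups of two, exact values."""
    values = pd.DataFrame(
        [[5.0, 5.5, 7.0, 7.5],
         [8.0, 8.2, 8.1, 7.9],
         [3.0, 3.1, 2.9, 3.2]],
        index=["GeneA", "GeneB", "GeneC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def tiny_design():
    return SampleTable(pd.DataFrame(
        {"group": ["a", "a", "b", "b"]},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id")))


@pytest.fixture(scope="session")
def small_compendium():
    spec = GeneratorSpec(n_genes=2000, n_populations=5, markers_per_population=100,
                         marker_effect=2.0, replicates=3, seed=1)
    return make_compendium(spec)


@pytest.fixture(scope="session")
def null_study():
    """2x2 study with no planted structure (5/5/6/8 samples)."""
    return make_study(GeneratorSpec(n_genes=3000, seed=11))


@pytest.fixture(scope="session")
def two_group_down():
    spec = GeneratorSpec(n_genes=2000, seed=5, n_down=150,
                         two_group_effect=1.0, sigma=0.25)
    return make_two_group(spec)
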