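import logging

import numpy as np
import pandas as pd
import pytest

from emtscape import synthetic_data as sd
from emtscape.genesets import GeneSet, GeneSetCollection
from emtscape.scoring import ExpressionMatrix

# generator warnings about dropped genes etc. are noise at test time
logging.getLogger("emtscape").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def five_state_spec():
    return sd.default_path_spec()


@pytest.fixture(scope="session")
def five_state_points(five_state_spec):
    """1200 (E, M) score pairs drawn from the five-state mixture, with truth."""
    rng = np.random.default_rng(2026)
    pts, labels = five_state_spec.sample_latent(1200, rng)
    return pts, labels


@pytest.fixture(scope="session")
def small_matrix():
    """20 genes x 6 samples of gamma-distributed abundance."""
    rng = np.random.default_rng(42)
    X = rng.gamma(2.0, 50.0, size=(20, 6))
    genes = [f"g{i}" for i in range(20)]
    return ExpressionMatrix(
        pd.DataFrame(X, index=genes, columns=[f"s{j}" for j in range(6)])
    )


@pytest.fixture(scope="session")
def small_sets(small_matrix):
    genes = small_matrix.gene_ids
    return GeneSetCollection.from_sets([GeneSet("S", frozenset(genes[3:8]))])
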