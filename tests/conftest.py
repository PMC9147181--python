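import numpy as np
import pytest
from hypothesis import settings

from rega.ga import GAConfig, evolve
from rega.synthetic import SyntheticSpec, generate_planted_dataset

settings.register_profile("default", derandomize=True, deadline=None,
                          max_examples=50)
settings.load_profile("default")

# Desk-scale GA settings used by the slower integration tests: small enough
# to finish in seconds, large enough for the planted signal to be found.
DESK_GA = dict(generations=10, population_size=10, n_subsets=4, subset_size=20)


@pytest.fixture(scope="session")
def planted():
    """The default planted fixture: 300 x (80 binary + 40 continuous), m=30."""
    matrix, y, informative = generate_planted_dataset(SyntheticSpec(seed=7))
    return matrix, y, informative


@pytest.fixture(scope="session")
def desk_evolution(planted):
    """One shared desk-scale GA run on the planted fixture (2:1:1 rows)."""
    matrix, y, informative = planted
    n = matrix.n_samples
    tr, va = np.arange(n // 2), np.arange(n // 2, 3 * n // 4)
    cfg = GAConfig(**DESK_GA, n_features=matrix.n_features, seed=11)
    result = evolve(cfg, matrix.values[tr], y[tr], matrix.values[va], y[va],
                    column_kinds=list(matrix.column_kinds))
    return result, informative, cfg
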