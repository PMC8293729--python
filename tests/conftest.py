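import numpy as np
import pytest

from oakmap.grids import GridSpec
from oakmap.synthetic import (
    TruthModel,
    generate_biophysical,
    generate_stands,
    generate_truth_and_inventory,
)


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(n_rows=60, n_cols=90, region_count=3)


@pytest.fixture(scope="session")
def stack(small_grid):
    return generate_biophysical(small_grid, seed=11)


@pytest.fixture(scope="session")
def landscape(stack):
    """Complete small landscape: stands, truth, occupancy and inventory."""
    stands = generate_stands(stack, seed=12)
    truth = TruthModel()
    occupancy, inventory = generate_truth_and_inventory(stands, stack, truth, seed=13)
    return {
        "stack": stack,
        "stands": stands,
        "truth": truth,
        "occupancy": occupancy,
        "inventory": inventory,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
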