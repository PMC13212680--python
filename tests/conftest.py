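import numpy as np
import pytest
from hypothesis import settings

import kremap as km

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_region():
    """20x20 region, 1 km cells, 20 block groups — fast shared fixture."""
    return km.make_region(n_rows=20, n_cols=20, cell_size=1000.0, n_groups=20, seed=42)


@pytest.fixture(scope="session")
def study_region():
    """The default 40x40 study region used by calibration/recovery tests."""
    return km.make_region(seed=1)


def uniform_pop(n_rows, n_cols, per_cell, cell_size=1000.0):
    spec = km.GridSpec(0.0, 0.0, cell_size, n_rows, n_cols)
    return km.PopulationGrid(spec, np.full((n_rows, n_cols), float(per_cell)))
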