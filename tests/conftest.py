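import numpy as np
import pytest

import chondrosim as cs


@pytest.fixture(scope="session")
def params() -> cs.ModelParameters:
    return cs.DEFAULT_PARAMETERS


@pytest.fixture()
def small_grid() -> cs.Grid:
    return cs.Grid(n_r=10, n_z=8)


@pytest.fixture(scope="session")
def default_trajectory() -> cs.Trajectory:
    """The full 14-day default impact scenario (shared: it is the baseline
    for the refinement, qualitative-pattern and sensitivity checks)."""
    cfg = cs.SimulationConfig()
    return cs.simulate(cfg, cfg.strain_field())


@pytest.fixture()
def small_strain(small_grid) -> cs.StrainField:
    return cs.synthetic_strain_field(cs.SyntheticStrainParams(), small_grid)
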