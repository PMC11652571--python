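import numpy as np
import pytest

from edge_salience import (
    RunConfig,
    build_experiment1,
    build_experiment2,
    default_layout,
)
from edge_salience.io_cli import build_design, simulate


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def exp1_blocks(layout):
    return build_experiment1(layout, master_seed=11)


@pytest.fixture(scope="session")
def exp2_blocks(layout):
    return build_experiment2(layout, master_seed=11)


@pytest.fixture(scope="session")
def small_exp1_responses():
    """A quick 8-participant cohort on the full Experiment-1 design."""
    cfg = RunConfig(experiment=1, n_participants=8, master_seed=5)
    return simulate(cfg, build_design(cfg))


@pytest.fixture(scope="session")
def small_exp2_responses():
    cfg = RunConfig(experiment=2, n_participants=8, master_seed=5)
    return simulate(cfg, build_design(cfg))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
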