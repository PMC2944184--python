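from pathlib import Path

import numpy as np
import pytest

from divtempo import parse_newick
from divtempo.fixtures import make_fixtures
from divtempo.treesim import yule_gamma_sample

DATA_DIR = Path(__file__).parent / "data" / "fixtures"

#: master seed used by the deterministic Monte-Carlo suites
SUITE_SEED = 20100914


@pytest.fixture(scope="session")
def fixture_set():
    return make_fixtures()


@pytest.fixture(scope="session")
def data_dir():
    return DATA_DIR


@pytest.fixture(scope="session")
def complete_null_90():
    """10,000 gamma draws from complete-sampling pure-birth trees of 90 tips.

    Shared by the null-calibration checks (critical value, test size,
    standard-normal convergence).
    """
    rng = np.random.default_rng(SUITE_SEED)
    return yule_gamma_sample(90, 90, 10_000, rng)


@pytest.fixture()
def tree3():
    return parse_newick("((A:1.0,B:1.0):1.0,C:2.0);")


def random_chronogram(n_tips, seed, birth_rate=1.0):
    from divtempo.treesim import simulate_yule

    return simulate_yule(n_tips, birth_rate, seed)
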