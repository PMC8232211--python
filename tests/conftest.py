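"""Shared fixtures.

The heavy D1 trajectories (the ones the physics checks are built on) are
session-scoped so each is propagated exactly once per test run.
"""

import numpy as np
import pytest

from b850sim import protocols
from b850sim.fixtures import fixture_suite
from b850sim.hamiltonian import coupling_matrix, make_bath


@pytest.fixture(scope="session")
def bath():
    return make_bath("linear_dispersion")


@pytest.fixture(scope="session")
def chain3():
    return fixture_suite("chain3")


@pytest.fixture(scope="session")
def hex7():
    return fixture_suite("hex7")


@pytest.fixture(scope="session")
def chain3_H(chain3):
    return coupling_matrix(chain3)


@pytest.fixture(scope="session")
def case2_chain3_2ps():
    """Bright-state (Case II) run on the 3-ring chain, 2 ps, dt = 0.05 fs."""
    _, traj = protocols.run_case("chain", n_rings=3, case=2, t_end_fs=2000.0)
    return traj


@pytest.fixture(scope="session")
def case1_chain3_1ps():
    """Dark-state (Case I) run on the 3-ring chain, 1 ps."""
    _, traj = protocols.run_case("chain", n_rings=3, case=1, t_end_fs=1000.0)
    return traj


@pytest.fixture(scope="session")
def case2_chain11_1ps():
    """Case II on the 11-ring chain (central ring), 1 ps."""
    return protocols.run_case("chain", n_rings=11, case=2, t_end_fs=1000.0)


@pytest.fixture(scope="session")
def case2_hex7_700fs():
    """Case II on the 7-ring hexagonal array, 700 fs."""
    _, traj = protocols.run_case("hexagonal", case=2, t_end_fs=700.0)
    return traj


@pytest.fixture(scope="session")
def case2_chain5_1ps():
    return protocols.run_case("chain", n_rings=5, case=2, t_end_fs=1000.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20210614)
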