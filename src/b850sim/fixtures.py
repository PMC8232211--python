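"""Small deterministic fixtures used by the test suite and the CLI.

All fixtures are generated programmatically — nothing is downloaded or
read from disk.
"""

from __future__ import annotations

import numpy as np

from . import afa, geometry, hamiltonian

__all__ = ["fixture_suite", "FIXTURES"]


def _dimer():
    """Two-site system with analytic eigensplitting 2J."""
    J = 50.0
    mat = np.array([[0.0, J], [J, 0.0]])
    return hamiltonian.ExcitonHamiltonian(J=mat, n_rings=1, n_sites_per_ring=2)


def _ring1():
    return geometry.build_nanoarray("chain", n_rings=1)


def _chain3():
    return geometry.build_nanoarray("chain", n_rings=3)


def _hex7():
    """Seven-ring hexagonal layout: one central ring plus six neighbors."""
    return geometry.build_nanoarray("hexagonal", n_shells=1)


def _fbm_h05():
    return afa.fbm_generator(0.5, 2**12, seed=850)


def _bath_default():
    return hamiltonian.make_bath("linear_dispersion")


def _rate_grid_small():
    """Logarithmic K/k ratio grid for hopping-model sweeps."""
    return np.logspace(-4, 0, 9)


FIXTURES = {
    "dimer": _dimer,
    "ring1": _ring1,
    "chain3": _chain3,
    "hex7": _hex7,
    "fbm_h05": _fbm_h05,
    "bath_default": _bath_default,
    "rate_grid_small": _rate_grid_small,
}


def fixture_suite(name: str):
    """Instantiate a registered fixture by name."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return builder()
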