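"""Shared fixtures.

Forward FE simulations are the expensive ingredient, so every curve that
more than one test consumes is computed once per session here (at the
coarse screening mesh unless the check specifically needs the production
level).
"""

from __future__ import annotations

import numpy as np
import pytest

from nemaindent.geometry import build_geometry
from nemaindent.materials import ElasticInput, from_engineering
from nemaindent.mesh import generate_mesh
from nemaindent.simulate import run_afm_indentation


@pytest.fixture(scope="session")
def geometry():
    return build_geometry()


@pytest.fixture(scope="session")
def mesh_l0(geometry):
    return generate_mesh(geometry, 0)


@pytest.fixture(scope="session")
def mesh_l1(geometry):
    return generate_mesh(geometry, 1)


@pytest.fixture(scope="session")
def soft_params():
    """Cuticle-like near-incompressible neo-Hookean material."""
    return from_engineering(ElasticInput(E=150.0, nu=0.49))


@pytest.fixture(scope="session")
def bdm_curve_l0():
    """Forward BDM-mean curve at the coarse level (shared across tests)."""
    return run_afm_indentation(
        moduli_kPa=(150.0, 1200.0, 840.0), set_force_nN=450.0, level=0
    )


@pytest.fixture(scope="session")
def high_salt_curve_l0():
    return run_afm_indentation(
        moduli_kPa=(90.0, 650.0, 76.0), set_force_nN=450.0, level=0
    )


@pytest.fixture(scope="session")
def aldicarb_curve_l0():
    return run_afm_indentation(
        moduli_kPa=(140.0, 950.0, 94.0), set_force_nN=450.0, level=0
    )


@pytest.fixture(scope="session")
def salt_control_curve_l0():
    return run_afm_indentation(
        moduli_kPa=(105.0, 390.0, 880.0), set_force_nN=450.0, level=0
    )


@pytest.fixture(scope="session")
def alt_moduli_curve_l0():
    """The 'wrong-compartment' alternative (muscle softened, pseudocoelom
    stiffened) used as the negative control for curve shape."""
    return run_afm_indentation(
        moduli_kPa=(150.0, 900.0, 1400.0), set_force_nN=450.0, level=0
    )


def rel_err(a, b):
    return abs(a - b) / abs(b)
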