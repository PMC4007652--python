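"""Shared fixtures: synthetic structures built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from phosphoconform import synthetic_data as syn
from phosphoconform.sasa_engine import SASAParams


@pytest.fixture(scope="session")
def helix20():
    return syn.build_ideal_helix("A" * 20)


@pytest.fixture(scope="session")
def helix50():
    return syn.build_ideal_helix("ADEFGHIKLMNQRSTVWYAD" * 2 + "ADEFGHIKLM")


@pytest.fixture(scope="session")
def extended12():
    return syn.build_extended_peptide("A" * 12)


@pytest.fixture(scope="session")
def hairpin():
    return syn.build_beta_hairpin(6)


@pytest.fixture(scope="session")
def globule():
    """Verified bundle: core octapeptide rSASA < 0.1, surface > 0.4."""
    return syn.build_globule(seed=1)


@pytest.fixture(scope="session")
def dimer():
    """Verified interface fixture: window buried in the assembly, exposed
    on the monomer."""
    return syn.build_interface_dimer(seed=1)


@pytest.fixture(scope="session")
def arm_fixture():
    """Verified dynamics fixture: site disallowed at input, rescued by a
    low-energy conformer."""
    return syn.build_floppy_arm(seed=3)


@pytest.fixture(scope="session")
def default_params():
    return SASAParams()


@pytest.fixture(scope="session")
def fast_params():
    return SASAParams(n_sphere_points=240)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
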