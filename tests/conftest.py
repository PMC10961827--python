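"""Shared fixtures: idealized builds reused across the suite."""

import warnings

import numpy as np
import pytest

from g4kit.builder import HelicalParams, build_g4, build_tetrad
from g4kit.topology import analyze_topology

TWIST_RH = 29.0    # reference right-handed inter-tetrad twist, deg
TWIST_LH = -27.0   # reference left-handed twist, deg


def _core(twist, progression):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_g4(HelicalParams(twist_deg=twist, progression=progression,
                                      loop_lengths=(0, 0, 0)))


@pytest.fixture(scope="session")
def rh_minus():
    """Stable right-handed fold: +29 deg twist, (-) progression."""
    return _core(TWIST_RH, "-")


@pytest.fixture(scope="session")
def lh_plus():
    """Stable left-handed fold: -27 deg twist, (+) progression."""
    return _core(TWIST_LH, "+")


@pytest.fixture(scope="session")
def rh_plus():
    return _core(TWIST_RH, "+")


@pytest.fixture(scope="session")
def lh_minus():
    return _core(TWIST_LH, "-")


@pytest.fixture(scope="session")
def t1_structure():
    """Single-chain two-layer G4 with single-thymine (T1) loops."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_g4(HelicalParams(twist_deg=TWIST_RH, progression="-",
                                      loop_lengths=(1, 1, 1)))


@pytest.fixture(scope="session")
def tetrad_model():
    return build_tetrad()


@pytest.fixture(scope="session")
def rh_minus_topology(rh_minus):
    return analyze_topology(rh_minus)


@pytest.fixture(scope="session")
def lh_plus_topology(lh_plus):
    return analyze_topology(lh_plus)


def mirror(structure):
    """Negate the x coordinate of every atom (improper reflection)."""
    from g4kit.core import Structure
    models = []
    for m in structure.models:
        c = m.coords.copy()
        c[:, 0] *= -1.0
        models.append(m.with_coords(c))
    return Structure(models)
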