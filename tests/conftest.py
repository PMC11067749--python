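"""Shared fixtures: everything is generated, nothing is read from disk."""

import numpy as np
import pytest

from aspher.fixtures import (SyntheticSpec, fixture_multipoles,
                             fixture_structure, simulate_reflections)


@pytest.fixture(scope="session")
def structure():
    return fixture_structure()


@pytest.fixture(scope="session")
def models_databank():
    return fixture_multipoles("databank")


@pytest.fixture(scope="session")
def electron_data(structure, models_databank):
    """Noise-free electron amplitudes from the databank tier (d_min 0.8 A)."""
    spec = SyntheticSpec(d_min=0.8, completeness=1.0, noise="none", seed=11)
    refl, ledger = simulate_reflections(spec, structure, models_databank)
    return refl, ledger


@pytest.fixture(scope="session")
def static_xray_data(models_databank):
    """Phased X-ray amplitudes at frozen geometry, ADPs = 0, scale 1."""
    st = fixture_structure()
    for s in st.sites:
        s.u_aniso = None
        s.u_iso = 0.0
    spec = SyntheticSpec(d_min=0.8, completeness=1.0, noise="none", seed=2,
                         radiation="xray")
    refl, _ = simulate_reflections(spec, st, models_databank)
    return st, refl


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
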