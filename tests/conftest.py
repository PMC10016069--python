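"""Shared fixtures: small protocols and phantoms reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from ficmap.morphometry import compute_morphometry
from ficmap.synthetic import (
    PhantomSpec,
    hcp_like_protocol,
    make_microstructure_phantom,
    make_phantom_surfaces,
)


@pytest.fixture(scope="session")
def protocol():
    """Three-shell protocol (b = 1000/2000/3000, 24 directions each)."""
    return hcp_like_protocol(n_per_shell=24, n_b0=6, seed=12345)


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom_surfaces(phantom_spec):
    return make_phantom_surfaces(phantom_spec)


@pytest.fixture(scope="session")
def phantom_volumes(phantom_spec, phantom_surfaces):
    return make_microstructure_phantom(phantom_spec, phantom_surfaces)


@pytest.fixture(scope="session")
def phantom_morphometry(phantom_surfaces):
    return compute_morphometry(phantom_surfaces)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
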