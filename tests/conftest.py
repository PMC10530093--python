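"""Shared fixtures: expensive model profiles and synthetic bundles are
computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from rnawaxs import (build_a_form_helix, build_uau_triplex, debye_profile,
                     parse_construct_spec)
from rnawaxs.synthetic import NoiseConfig, make_basis_set, simulate_experiment


@pytest.fixture(scope="session")
def triplex24():
    """Default idealized U.A-U triplex, 24 triples."""
    return build_uau_triplex(24)


@pytest.fixture(scope="session")
def triplex24_profile(triplex24):
    """Debye profile of the default triplex on the wide-angle grid."""
    q = 0.5 + 0.005 * np.arange(int(round((2.2 - 0.5) / 0.005)) + 1)
    return debye_profile(triplex24, q)


@pytest.fixture(scope="session")
def hairpin62():
    """29-bp A-form hairpin with a 4-nt loop (62 nt)."""
    return build_a_form_helix(29, 4)


@pytest.fixture(scope="session")
def hairpin62_profile(hairpin62):
    q = 0.3 + 0.005 * np.arange(int(round((2.2 - 0.3) / 0.005)) + 1)
    return debye_profile(hairpin62, q)


@pytest.fixture(scope="session")
def basis_and_models():
    return make_basis_set(seed=0)


@pytest.fixture(scope="session")
def basis(basis_and_models):
    return basis_and_models[0]


@pytest.fixture(scope="session")
def bundle(basis):
    """Scaled-down synthetic time course: 2,000 frames per point, 5%
    ice contamination, fixed seed."""
    return simulate_experiment(basis=basis, n_frames=2000,
                               noise=NoiseConfig(ice_rate=0.05), seed=1)


@pytest.fixture(scope="session")
def reduced_series(bundle):
    """Reduced profiles for every time point of the session bundle."""
    from rnawaxs.reduction import reduce_timepoint

    out = []
    for t in bundle.time_points_ms:
        s, b = bundle.stacks[t]
        out.append((t, reduce_timepoint(s, b)))
    return out
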