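"""Shared fixtures: a desk-scale source space, head model and lead field.

Everything is generated programmatically; the session scope keeps the
spherical-harmonic series evaluation out of every individual test.
"""

import numpy as np
import pytest

from stfmri_esi import (
    SphericalHeadModel,
    compute_lead_field,
    fibonacci_cap_electrodes,
    make_icosphere_source_space,
)


@pytest.fixture(scope="session")
def src162():
    """162-vertex icosphere source space (subdivisions=2)."""
    return make_icosphere_source_space(2)


@pytest.fixture(scope="session")
def src42():
    """Coarse 42-vertex mesh for cluster/threshold tests."""
    return make_icosphere_source_space(1)


@pytest.fixture(scope="session")
def head():
    return SphericalHeadModel()


@pytest.fixture(scope="session")
def electrodes(head):
    return fibonacci_cap_electrodes(32, radius=head.radii[2])


@pytest.fixture(scope="session")
def leadfield(head, electrodes, src162):
    names, pos = electrodes
    return compute_lead_field(head, pos, src162, channel_names=names)
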