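"""Shared fixtures: phantoms and flow fields are expensive, so the coarse
default phantom (4 mm) and its steady flow solve are session-scoped and
reused across scenario tests; the 2 mm phantom is built once for the
flow-field acceptance checks."""

import numpy as np
import pytest

from braintx.flow import HydraulicParams, solve_interstitial_flow
from braintx.phantom import PhantomSpec, build_phantom
from braintx.scenarios import ModelBundle


@pytest.fixture(scope="session")
def coarse_phantom():
    """Default geometry at 4 mm: fast enough for transport scenarios."""
    return build_phantom(PhantomSpec.default(voxel_spacing=4e-3))


@pytest.fixture(scope="session")
def phantom_2mm():
    return build_phantom(PhantomSpec.default(voxel_spacing=2e-3))


@pytest.fixture(scope="session")
def bundle():
    return ModelBundle()


@pytest.fixture(scope="session")
def coarse_flow(coarse_phantom, bundle):
    return solve_interstitial_flow(coarse_phantom, bundle.hydraulics)


@pytest.fixture(scope="session")
def flow_2mm(phantom_2mm, bundle):
    return solve_interstitial_flow(phantom_2mm, bundle.hydraulics)


@pytest.fixture(scope="session")
def hydraulics():
    return HydraulicParams.default()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
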