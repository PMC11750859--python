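import numpy as np
import pytest

from mossyfiber.channels import load_profile, make_variant
from mossyfiber.morphology import build_mossy_fiber


@pytest.fixture(scope="session")
def default_model():
    return build_mossy_fiber()


@pytest.fixture(scope="session")
def generic_profile():
    return load_profile("generic")


@pytest.fixture(scope="session")
def inactivating_channels(generic_profile):
    return make_variant("inactivating", profile=generic_profile)


@pytest.fixture(scope="session")
def isopotential_model():
    """Two identical fat segments: electrically one compartment."""
    cfg = {"geometry": {
        "soma": {"diameter_um": 10.0, "length_um": 10.0},
        "axon": {"count": 1, "length_um": 10.0, "diameter_um": 10.0},
        "bouton": {"count": 0},
        "segments_per_um": 0.1,
    }}
    return build_mossy_fiber(cfg)


@pytest.fixture(scope="session")
def thin_cable_model():
    """401-segment uniform 0.2 um cable (1 um soma stub + 400 um axon)."""
    cfg = {"geometry": {
        "soma": {"diameter_um": 0.2, "length_um": 1.0},
        "axon": {"count": 1, "length_um": 400.0, "diameter_um": 0.2},
        "bouton": {"count": 0},
    }}
    return build_mossy_fiber(cfg)
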