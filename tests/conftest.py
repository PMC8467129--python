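import numpy as np
import pytest

from sfdikit.keystone import ProjectorGeometry


@pytest.fixture
def rig_geometry() -> ProjectorGeometry:
    """The calibrated projector pose of the reference rig."""
    return ProjectorGeometry(
        fu=2116.8, fv=2122.4, cu=670.4, cv=-186.8, h=527.0, alpha=20.0, beta=0.5
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
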