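import numpy as np
import pytest

from petquant.kinetics import TwoTissueParams
from petquant.synthetic_data import (
    AifModel,
    SyntheticSubjectSpec,
    generate_dynamic_phantom,
)

#: nine dynamic frame mid-times used for joint quantification (min)
DYNAMIC_GRID = np.array([1.5, 3.0, 5.0, 7.0, 11.0, 14.0, 17.0, 20.0, 25.0])

#: printed rate constants for the two bilateral-prosthesis patients
PATIENT4_SUSPECTED = TwoTissueParams(K1=0.488, k2=1.082, k3=1.234, k4=0.569, vB=0.05)
PATIENT4_CONTRA = TwoTissueParams(K1=0.019, k2=0.053, k3=0.004, k4=6.431, vB=0.05)
PATIENT2_SUSPECTED = TwoTissueParams(K1=0.33, k2=0.358, k3=0.225, k4=0.457, vB=0.05)
PATIENT2_CONTRA = TwoTissueParams(K1=0.034, k2=0.076, k3=0.0, k4=5.122, vB=0.05)


@pytest.fixture(scope="session")
def default_aif():
    """Dense default blood input curve."""
    return AifModel().dense_curve(50.0)


@pytest.fixture(scope="session")
def noise_free_spec():
    return SyntheticSubjectSpec(seed=7, noise_scale=0.0)


@pytest.fixture(scope="session")
def noise_free_phantom(noise_free_spec):
    """Noise-free default phantom at full resolution (shared: generation
    is the expensive part)."""
    return generate_dynamic_phantom(noise_free_spec)


@pytest.fixture
def small_spec():
    """Small-volume spec for geometry-light tests."""
    return SyntheticSubjectSpec(seed=3, noise_scale=0.0, volume_shape=(64, 64, 64))
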