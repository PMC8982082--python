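import numpy as np
import pytest

from sdctperf import VoxelVolume, extract_case_features, generate_phantom, preset_profile


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_volume(values, kind=None, spacing=(1.0, 1.0, 1.0)):
    return VoxelVolume(np.asarray(values), spacing=spacing, kind=kind)


@pytest.fixture(scope="session")
def g4_phantom():
    return generate_phantom(preset_profile("g4"), (48, 48, 48), seed=11)


@pytest.fixture(scope="session")
def g3_phantom():
    return generate_phantom(preset_profile("g3"), (48, 48, 48), seed=12)


@pytest.fixture(scope="session")
def g1_phantom():
    return generate_phantom(preset_profile("g1"), (48, 48, 48), seed=13)


@pytest.fixture(scope="session")
def g4_features(g4_phantom):
    return extract_case_features(g4_phantom)
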