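import numpy as np
import pytest

from genrefmri import synth, features


@pytest.fixture(scope="session")
def archetypes():
    return synth.make_archetypes(4, seed=11)


@pytest.fixture(scope="session")
def short_clip(archetypes):
    return synth.synthesize_clip(archetypes[0], duration=6.0, seed=21)


@pytest.fixture(scope="session")
def short_cochleogram(short_clip):
    return features.cochleogram(short_clip)


@pytest.fixture(scope="session")
def tiny_cochleogram():
    """8 channels x 60 frames of seeded random energies."""
    rng = np.random.default_rng(3)
    cfs = np.geomspace(100.0, 8000.0, 8)
    return features.Cochleogram(rng.random((60, 8)), 0.010, 0.025, cfs)
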