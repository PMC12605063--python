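import numpy as np
import pytest

from chordaffect import chord_stimuli as cs
from chordaffect import synth_eeg as se
from chordaffect.montage import adjacency_matrix, standard_montage


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


@pytest.fixture(scope="session")
def adjacency(montage):
    return adjacency_matrix(montage)


@pytest.fixture(scope="session")
def stimuli():
    return cs.build_stimulus_set()


@pytest.fixture(scope="session")
def schedule(stimuli):
    return cs.make_schedule(stimuli, repetitions=5, seed=0)


@pytest.fixture(scope="session")
def truth():
    return se.GroundTruth()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
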