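import numpy as np
import pytest

import biomotion as bm


@pytest.fixture(scope="session")
def gdict8():
    """Standard 8-orientation, single-scale Gabor dictionary."""
    return bm.build_dictionary(8, 1, 17)


@pytest.fixture(scope="session")
def tiny_dataset():
    """4 subjects x 6 actions x 20 frames — small but fully articulated."""
    return bm.make_dataset(4, frames_per_video=20, seed=11)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_dataset):
    """Bundle trained on 2 of the 4 subjects (subject-disjoint)."""
    train_v, test_v = bm.prototypes.train_split(tiny_dataset, 2, seed=0)
    bundle = bm.train(train_v, bm.PipelineConfig(seed=0))
    return bundle, train_v, test_v
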