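import numpy as np
import pytest

from aswnet.io import InstanceMask, ProbMap
from aswnet.preprocess import instance_to_three_class
from aswnet.synthetic import SynthConfig, generate_nuclei_image


@pytest.fixture(scope="session")
def small_sample():
    """A 256x256 field with 15 nuclei, 30% clumped."""
    cfg = SynthConfig(image_height=256, image_width=256, n_nuclei=15,
                      clump_fraction=0.3, rng_seed=7)
    return generate_nuclei_image(cfg)


def ideal_prob_map(truth: InstanceMask, boundary_width: int = 2) -> ProbMap:
    """A perfect 3-class probability map constructed from ground truth."""
    lab3 = instance_to_three_class(truth, boundary_width)
    probs = np.zeros((3,) + truth.shape, dtype=np.float32)
    for c in range(3):
        probs[c] = lab3.classes == c
    return ProbMap(probs=probs)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def shifted_square_pair():
    """2x2 truth square and the same square shifted one pixel right."""
    truth = np.zeros((6, 6), dtype=np.int32)
    truth[2:4, 2:4] = 1
    pred = np.zeros((6, 6), dtype=np.int32)
    pred[2:4, 3:5] = 1
    return InstanceMask(pred), InstanceMask(truth)
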