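import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import tonguefusion as tf


@pytest.fixture
def rng():
    return np.random.default_rng(20240624)


@pytest.fixture
def random_image(rng):
    """A 64x64 float image with full [0, 255] dynamic range."""
    return rng.uniform(0, 255, (64, 64))


@pytest.fixture(scope="session")
def small_cohort():
    """Six subjects (3 per group), deterministic."""
    return tf.generate_cohort(tf.CohortConfig(n_per_group=3, seed=123))


@pytest.fixture(scope="session")
def rendered_pair(small_cohort):
    return tf.render_tongue_pair(small_cohort[0], seed=7)
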