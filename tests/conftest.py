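import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/_oracles.py

from mlhmax import stimuli


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140924)


@pytest.fixture(scope="session")
def small_train_set():
    """Tiny cross-fin set shared by feature-hierarchy tests."""
    return stimuli.generate_set("train_cross", "HV", seed=7, n_per_category=3)
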