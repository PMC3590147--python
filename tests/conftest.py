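import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

from orfclean import CorrectionParams, generate_family

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return CorrectionParams()


@pytest.fixture(scope="session")
def small_family():
    """Ten 120-AA orthologs at ~0.95 identity with conserved termini."""
    return generate_family("fam", 10, 120, 0.95, np.random.default_rng(7))
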