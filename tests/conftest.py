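from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FIXTURES = Path(__file__).resolve().parent.parent / "fixtures"


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def table2_path():
    return FIXTURES / "table2_markers.tsv"


def random_dna(rng, length, probs=(0.28, 0.22, 0.22, 0.28)):
    return "".join(rng.choice(list("ACGT"), size=length, p=list(probs)))
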