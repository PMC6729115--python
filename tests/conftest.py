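import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import attriphase as ap

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def small_dataset():
    """N=10, K=3: exits {1: 2 people, 2: 2 people}, 6 completers."""
    records = (
        [(f"d1_{i}", 1) for i in range(2)]
        + [(f"d2_{i}", 2) for i in range(2)]
        + [(f"c_{i}", ap.COMPLETED) for i in range(6)]
    )
    return ap.DropoutDataset.from_records(records, ap.SurveyDesign(3))


def random_dataset(rng, n=40, K=6):
    """Random monotone dropout data without any hazard structure."""
    codes = rng.integers(1, K + 2, size=n)
    ids = np.array([f"p{i}" for i in range(n)], dtype=object)
    return ap.DropoutDataset(ap.SurveyDesign(K), ids, codes)
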