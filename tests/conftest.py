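import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def trials_from_counts(levels, n_per_level, n_correct, subject="S1", condition="audio"):
    """Build a trial table with exact correct/incorrect counts per level.

    Levels are positive; correct trials respond "up", incorrect "down".
    """
    rows = []
    for x, n, c in zip(levels, n_per_level, n_correct):
        rows += [(subject, condition, x, "up")] * int(c)
        rows += [(subject, condition, x, "down")] * int(n - c)
    return pd.DataFrame(rows, columns=["subject_id", "condition", "level", "response"])


@pytest.fixture
def counts_builder():
    return trials_from_counts


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
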