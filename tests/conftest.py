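import numpy as np
import pandas as pd
import pytest

from fixerp.core import EVENT_COLUMNS
from fixerp.synth import CohortConfig, generate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_events(rows):
    """Build an event table from (type, onset, dur_ms, aoi, amp, prior) tuples."""
    table = pd.DataFrame(rows, columns=["event_type", "onset_sample",
                                        "duration_ms", "aoi", "amplitude",
                                        "prior_saccade_amplitude"])
    table["peak_velocity"] = np.nan
    return table[list(EVENT_COLUMNS)]


@pytest.fixture(scope="session")
def short_subject():
    """One 40-s simulated subject with the canonical 592.89 ms offset."""
    cfg = CohortConfig(duration_s=40.0)
    return generate_subject("sub-01", cfg, seed=424242, offset_ms=592.89)
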