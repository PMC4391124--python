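import numpy as np
import pandas as pd
import pytest

from frailscreen.accelerometry import summarize_all
from frailscreen.phenotype import apply_exclusions
from frailscreen.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-participant synthetic cohort with its accelerometer records."""
    cfg = SyntheticConfig(n_participants=600, seed=20260930)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def retained_cohort(small_cohort):
    """The small cohort after accelerometer summaries and study exclusions."""
    cohort, accel = small_cohort
    summaries = summarize_all(accel)
    retained, log = apply_exclusions(cohort, summaries)
    return retained, log


def make_accel_days(wear_list, aee_list, pid="P1"):
    return pd.DataFrame(
        {
            "participant_id": pid,
            "day_index": np.arange(1, len(wear_list) + 1),
            "wear_minutes": wear_list,
            "aee": aee_list,
        }
    )
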