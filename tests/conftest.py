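import numpy as np
import pandas as pd
import pytest

from pinebeetle.proportions import TrialRecord, trials_to_frame


@pytest.fixture
def two_group_trials() -> pd.DataFrame:
    """Grouped binomial data: species x with 30/50, species y with 10/50."""
    return trials_to_frame([
        TrialRecord(stage="bark", year=2013, species="x", host_class="novel",
                    tree_id="t1", unit_id="u1", n_exposed=50, n_success=30),
        TrialRecord(stage="bark", year=2013, species="y", host_class="historical",
                    tree_id="t2", unit_id="u2", n_exposed=50, n_success=10),
    ])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130804)
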