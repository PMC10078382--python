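import numpy as np
import pandas as pd
import pytest

from streaklab.stimuli import build_stimulus_set


@pytest.fixture(scope="session")
def stimset():
    """One default balanced 18-trial session shared across tests."""
    return build_stimulus_set(11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_response_table(rows):
    """Assemble a minimal valid response table from (pid, cond, fmt, trial, role, L, seq, resp)."""
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "condition",
            "format",
            "trial_index",
            "role",
            "terminal_streak",
            "sequence",
            "response",
        ],
    ).assign(study_tag="test")
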