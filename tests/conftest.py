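import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from moralcan.data import Battery, CELL_DESIGN

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


def battery_from_counts(cell_actions, trials_per_cell=6, group=None, trait=None):
    """Build a battery from per-participant action counts.

    ``cell_actions``: mapping participant id -> 4 action counts (one per
    cell).  Deterministic: the first ``a`` trials in a cell are actions.
    """
    rows = []
    for pid, actions in cell_actions.items():
        for cell, a in zip(range(1, 5), actions):
            norm, cons = CELL_DESIGN[cell]
            for t in range(trials_per_cell):
                rows.append(
                    {
                        "participant": pid,
                        "dilemma": f"d{cell}_{t + 1}",
                        "norm": norm,
                        "consequence": cons,
                        "response": 1 if t < a else 0,
                    }
                )
    df = pd.DataFrame(rows)
    if group is not None:
        df["group"] = df["participant"].map(group)
    if trait is not None:
        df["trait"] = df["participant"].map(trait)
    return Battery(df)


@pytest.fixture
def two_participant_battery():
    """Two participants, 6 trials/cell: a pure consequentialist pattern
    (6,0,6,0) and a pattern mixing norms in (0,0,6,6)."""
    return battery_from_counts({"s01": (6, 0, 6, 0), "s02": (0, 0, 6, 6)})


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
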