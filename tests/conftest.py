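import numpy as np
import pandas as pd
import pytest

import sdtlatent as sl


@pytest.fixture(scope="session")
def small_complete_table() -> pd.DataFrame:
    """40 persons x 30 items, complete design, mixed m, fixed seed."""
    truth = sl.make_truth(seed=424, n_subjects=40, n_items=30, design="complete",
                          paired=False)
    return sl.simulate_responses(truth)


@pytest.fixture(scope="session")
def small_truth() -> sl.SimulationTruth:
    return sl.make_truth(seed=424, n_subjects=40, n_items=30, design="complete",
                         paired=False)


@pytest.fixture()
def tiny_table() -> pd.DataFrame:
    """Hand-written 2-person x 2-item table."""
    return pd.DataFrame(
        {
            "person_id": ["p1", "p1", "p2", "p2"],
            "item_id": ["a", "b", "a", "b"],
            "m": [2, 2, 2, 2],
            "score": [1, 0, 0, 1],
        }
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
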