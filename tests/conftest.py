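import numpy as np
import pandas as pd
import pytest

from codonaffinity import genetic_code as gc


@pytest.fixture(scope="session")
def table():
    return gc.standard_table()


@pytest.fixture(scope="session")
def allocations(table):
    """Anticodon-middle-base allocations of the standard table (23)."""
    return gc.expand_assignments(table, "anticodon2")


def two_state_se(occupancy, mean_dwell_bound, n_total_frames):
    """Analytic standard error of the pooled occupancy estimate.

    For a stationary two-state Markov chain with switch probabilities
    q_bf = 1/dwell_bound and q_fb = 1/dwell_free, the variance of the
    time-average over n frames is p(1-p) * (2/(q_bf+q_fb) - 1) / n.
    """
    p = occupancy
    dwell_free = mean_dwell_bound * (1 - p) / p
    q = 1.0 / mean_dwell_bound + 1.0 / dwell_free
    return np.sqrt(p * (1 - p) * (2.0 / q - 1.0) / n_total_frames)


@pytest.fixture
def planted_matrix(table):
    """Adjusted-binding matrix whose every cognate anticodon-middle base is
    strictly the best binder."""
    rows = {}
    for aa in sorted(table):
        cognate = sorted(gc.cognate_bases(aa, "anticodon2", table))[0]
        vals = {b: 0.2 + 0.05 * i for i, b in enumerate(b for b in "ACGU" if b != cognate)}
        vals[cognate] = 0.9
        rows[aa] = vals
    return pd.DataFrame.from_dict(rows, orient="index")[list("ACGU")]
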