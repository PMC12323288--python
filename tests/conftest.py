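import numpy as np
import pandas as pd
import pytest

from vwpgaze.io import CONDITIONS, ScreenGeometry
from vwpgaze.preprocessing import BinnedFixationTensor
from vwpgaze.synthetic import (CohortSpec, GroupParams, NoiseParams,
                               simulate_cohort, simulate_cohort_tensor)

SAMPLE_DT = 1000.0 / 120.0


@pytest.fixture(scope="session")
def geometry():
    return ScreenGeometry()


def make_trial_frame(t_ms, x, y, valid=None):
    """Build a single-trial gaze frame with identical left/right eyes."""
    n = len(t_ms)
    valid = np.ones(n, dtype=int) if valid is None else np.asarray(valid, int)
    x = np.asarray(x, float).copy()
    y = np.asarray(y, float).copy()
    x[valid == 0] = np.nan
    y[valid == 0] = np.nan
    return pd.DataFrame({
        "participant_id": "p1", "trial_id": 0, "t_ms": np.asarray(t_ms, float),
        "lx": x, "ly": y, "rx": x, "ry": y,
        "l_valid": valid, "r_valid": valid,
    })


def tensor_from_array(data, groups=None):
    """Wrap a (P, T, B, C) array into a tensor with default labels."""
    data = np.asarray(data, float)
    p, t, b, c = data.shape
    assert c == len(CONDITIONS)
    if groups is None:
        groups = ["NT"] * p
    return BinnedFixationTensor(
        data, [f"p{k:03d}" for k in range(p)], list(range(t)),
        np.asarray(groups, object))


@pytest.fixture(scope="session")
def small_cohort():
    """Full-path simulated cohort, small but with all noise sources on."""
    spec = CohortSpec(n_per_group={"autistic": 4, "NT": 4}, seed=11)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def paper_scale_tensor_cohort():
    """Latent-path cohort at the study's group sizes (45 / 52)."""
    return simulate_cohort_tensor(CohortSpec(seed=7))
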