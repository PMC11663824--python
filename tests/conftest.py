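import numpy as np
import pandas as pd
import pytest

from snarcpipe.simulate import DIGITS, TRIAL_COLUMNS, GroupConfig


def make_trials(rows):
    """Build a trial frame from (pid, task, block, digit, side, correct, rt) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["participant_id", "task", "block", "digit", "response_side",
                 "correct", "rt_ms"],
    )
    df["group"] = "G"
    df["trial_index"] = np.arange(len(df))
    return df[TRIAL_COLUMNS]


def balanced_trials(pid="p1", task="PJ", rt_fn=None, n_per_side=2, rng=None):
    """Full-design trials: every digit x side cell filled with n_per_side trials.

    ``rt_fn(digit, side, k)`` supplies the RT; default 500 ms everywhere.
    """
    if rt_fn is None:
        rt_fn = lambda d, s, k: 500.0
    rows = []
    for d in DIGITS:
        for side in ("left", "right"):
            for k in range(n_per_side):
                rows.append((pid, task, 1, d, side, True, float(rt_fn(d, side, k))))
    return make_trials(rows)


def linear_drt_trials(pid="p1", task="PJ", intercept=0.0, slope=-10.0,
                      parity=0.0, base=600.0, n_per_side=2):
    """Noise-free trials whose dRT profile is exactly a + b*d + m*parity."""
    def rt(d, side, k):
        par = 0.5 if d % 2 == 0 else -0.5
        eff = intercept + slope * d + parity * par
        return base + (0.5 if side == "right" else -0.5) * eff

    return balanced_trials(pid, task, rt, n_per_side)


@pytest.fixture
def noise_free_config():
    return GroupConfig(
        group_label="G",
        n_participants=1,
        slope_mean=-10.0,
        slope_sd=0.0,
        marc_mean=0.0,
        marc_sd=0.0,
        base_rt_mean=600.0,
        base_rt_sd_between=0.0,
        noise_sd_within=0.0,
        tau_within=0.0,
        error_rate=0.0,
        lapse_rate=0.0,
        drt_intercept_mean=55.0,
    )
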