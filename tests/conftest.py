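"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pptn_tonic.task import TRIAL_COLUMNS, TaskConfig


@pytest.fixture
def task_config() -> TaskConfig:
    return TaskConfig(n_blocks=4)


def build_trials_frame(n: int, t_stim: float = 1.5, ft: float = 2.0,
                       st: float = 2.6, reward: float = 3.0,
                       with_fp: bool = True, rtit=None) -> pd.DataFrame:
    """A minimal success-trial table with constant event times."""
    rows = []
    for i in range(n):
        size = "large" if i % 2 == 0 else "small"
        rows.append({
            "trial_id": i, "block_id": i // 25, "index_in_block": i % 25 + 1,
            "reward_size": size,
            "ft_shape": "square" if size == "large" else "triangle",
            "fp_onset_s": t_stim if with_fp else np.nan,
            "ft_onset_s": ft if with_fp else t_stim,
            "st_onset_s": st, "reward_time_s": reward,
            "rtit_s": rtit[i] if rtit is not None else 0.1,
            "gaze_shift_time_s": t_stim + (rtit[i] if rtit is not None else 0.1),
            "outcome": "success", "free_reward_time_s": np.nan,
        })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def poisson_train(rng: np.random.Generator, rate: float, t0: float,
                  t1: float) -> np.ndarray:
    """Homogeneous Poisson spikes on [t0, t1) by exponential gaps (oracle)."""
    if rate <= 0:
        return np.empty(0)
    out = []
    t = t0 + rng.exponential(1.0 / rate)
    while t < t1:
        out.append(t)
        t += rng.exponential(1.0 / rate)
    return np.asarray(out)
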