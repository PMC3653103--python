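"""Simulation of a reward-biased visually guided saccade session.

A session is a sequence of blocks.  Within a block the mapping between the
fixation-target (FT) shape and the reward magnitude (large = 3 drops, small =
1 drop) is fixed; the mapping reverses between consecutive blocks, and block
lengths are drawn uniformly from a configurable range (20-30 trials by
default).  Each trial runs: intertrial interval -> initial stimulus (an
uninformative fixation point FP, or directly the FT) -> FT -> saccade target
(ST) -> reward.  The reaction time to fixate the initial target (RTit) may be
negative: the subject often shifts gaze to the screen centre in anticipation
of the stimulus.

All event times are seconds relative to trial start (the start of the
preceding intertrial interval), so the pre-stimulus baseline window is always
inside the trial's own span.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    """Raised for inconsistent task-configuration values."""


#: exact column order of the trial CSV dialect
TRIAL_COLUMNS = [
    "trial_id",
    "block_id",
    "index_in_block",
    "reward_size",
    "ft_shape",
    "fp_onset_s",
    "ft_onset_s",
    "st_onset_s",
    "reward_time_s",
    "rtit_s",
    "gaze_shift_time_s",
    "outcome",
    "free_reward_time_s",
]

#: alignment-event name -> trial column ("stim" resolves FP, else FT)
EVENT_COLUMNS = {
    "fp": "fp_onset_s",
    "ft": "ft_onset_s",
    "st": "st_onset_s",
    "reward": "reward_time_s",
    "gaze": "gaze_shift_time_s",
    "free_reward": "free_reward_time_s",
}


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the simulated saccade task.

    Defaults follow the task description: quasi-random block switching every
    20-30 trials, 400-800 ms FP fixation, 400-1500 ms FT fixation, reward
    delivered 100 or 300 ms after the ST disappears, a 1500 ms fixed
    intertrial interval (or 1.5-2 s jittered), and 3 vs 1 drops of juice.
    """

    task_variant: str = "with_fp"  # "with_fp" | "without_fp"
    n_blocks: int = 5
    block_length_range: tuple[int, int] = (20, 30)
    fp_fixation_range_s: tuple[float, float] = (0.4, 0.8)
    ft_fixation_range_s: tuple[float, float] = (0.4, 1.5)
    reward_delay_choices_s: tuple[float, ...] = (0.1, 0.3)
    iti_mode: str = "fixed"  # "fixed" | "jittered"
    iti_s: float = 1.5
    iti_range_s: tuple[float, float] = (1.5, 2.0)
    reward_drops: tuple[int, int] = (3, 1)  # (large, small)
    p_error: float = 0.1
    p_free_reward: float = 0.05
    # RTit ~ Normal(mean, sd) truncated to bounds; negative = anticipatory
    rtit_mean_s: float = -0.1
    rtit_sd_s: float = 0.25
    rtit_bounds_s: tuple[float, float] = (-1.5, 3.0)
    ft_shapes: tuple[str, str] = ("square", "triangle")
    saccade_rt_range_s: tuple[float, float] = (0.15, 0.35)
    st_directions_deg: tuple[float, ...] = (0.0, 180.0)

    def __post_init__(self) -> None:
        if self.task_variant not in ("with_fp", "without_fp"):
            raise ConfigError(f"unknown task_variant {self.task_variant!r}")
        if self.iti_mode not in ("fixed", "jittered"):
            raise ConfigError(f"unknown iti_mode {self.iti_mode!r}")
        for name in ("block_length_range", "fp_fixation_range_s",
                     "ft_fixation_range_s", "iti_range_s",
                     "saccade_rt_range_s", "rtit_bounds_s"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name}: min {lo} > max {hi}")
        if self.block_length_range[0] < 1 or self.n_blocks < 1:
            raise ConfigError("need at least one block of at least one trial")
        for name in ("iti_s", "rtit_sd_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if any(d <= 0 for d in self.reward_delay_choices_s):
            raise ConfigError("reward delays must be strictly positive")
        for name in ("p_error", "p_free_reward"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if self.reward_drops[0] <= self.reward_drops[1]:
            raise ConfigError("large reward must exceed small reward")
        if len(set(self.ft_shapes)) != 2:
            raise ConfigError("need two distinct FT shapes")


@dataclass
class TrialRecord:
    """Events and outcome of one behavioral trial (times re trial start)."""

    trial_id: int
    block_id: int
    index_in_block: int  # 1-based position within the block
    reward_size: str  # "large" | "small"
    ft_shape: str
    fp_onset_s: Optional[float]
    ft_onset_s: float
    st_onset_s: Optional[float]
    reward_time_s: Optional[float]
    rtit_s: float
    gaze_shift_time_s: float
    outcome: str  # "success" | "fixation_break" | "saccade_error"
    free_reward_time_s: Optional[float] = None
    st_direction_deg: Optional[float] = None

    @property
    def initial_stimulus_onset_s(self) -> float:
        """FP onset when the task variant shows one, FT onset otherwise."""
        return self.fp_onset_s if self.fp_onset_s is not None else self.ft_onset_s

    @property
    def end_s(self) -> float:
        """End of the simulated span: one second after the last event."""
        last = max(t for t in (self.ft_onset_s, self.st_onset_s,
                               self.reward_time_s, self.gaze_shift_time_s)
                   if t is not None)
        return last + 1.0


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      bounds: tuple[float, float]) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if bounds[0] <= x <= bounds[1]:
            return float(x)
    return float(np.clip(mean, *bounds))  # pragma: no cover - pathological sd


def generate_trial_sequence(config: TaskConfig, seed) -> list[TrialRecord]:
    """Draw a full session of trials; a pure function of (config, seed).

    The FT-shape/reward contingency reverses at every block boundary.  Error
    trials are truncated at the failed event (a fixation break drops the ST
    and the reward; a saccade error drops only the reward).  Free rewards
    occur in the intertrial interval with probability ``p_free_reward``.
    """
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    trial_id = 0
    for block_id in range(config.n_blocks):
        lo, hi = config.block_length_range
        length = int(rng.integers(lo, hi + 1))
        # contingency flips each block
        large_shape = config.ft_shapes[block_id % 2]
        for index in range(1, length + 1):
            if config.iti_mode == "fixed":
                iti = config.iti_s
            else:
                iti = float(rng.uniform(*config.iti_range_s))
            t_stim = iti
            rtit = _truncated_normal(rng, config.rtit_mean_s,
                                     config.rtit_sd_s, config.rtit_bounds_s)
            gaze = t_stim + rtit
            reward_size = "large" if rng.random() < 0.5 else "small"
            ft_shape = (large_shape if reward_size == "large"
                        else next(s for s in config.ft_shapes if s != large_shape))
            # fixation is acquired at the gaze shift, or at stimulus onset if
            # the gaze shift was anticipatory
            t_fix = max(t_stim, gaze)
            if config.task_variant == "with_fp":
                fp_onset: Optional[float] = t_stim
                ft_onset = t_fix + float(rng.uniform(*config.fp_fixation_range_s))
            else:
                fp_onset = None
                ft_onset = t_stim
            st_onset = (max(ft_onset, t_fix)
                        + float(rng.uniform(*config.ft_fixation_range_s)))
            outcome = "success"
            if rng.random() < config.p_error:
                outcome = ("fixation_break" if rng.random() < 0.5
                           else "saccade_error")
            reward_time: Optional[float] = None
            st: Optional[float] = st_onset
            direction: Optional[float] = float(rng.choice(config.st_directions_deg))
            if outcome == "fixation_break":
                st = None
                direction = None
            elif outcome == "success":
                saccade_rt = float(rng.uniform(*config.saccade_rt_range_s))
                delay = float(rng.choice(config.reward_delay_choices_s))
                reward_time = st_onset + saccade_rt + delay
            free_reward: Optional[float] = None
            if rng.random() < config.p_free_reward and t_stim > 0.4:
                free_reward = float(rng.uniform(0.1, t_stim - 0.2))
            trials.append(TrialRecord(
                trial_id=trial_id, block_id=block_id, index_in_block=index,
                reward_size=reward_size, ft_shape=ft_shape,
                fp_onset_s=fp_onset, ft_onset_s=ft_onset, st_onset_s=st,
                reward_time_s=reward_time, rtit_s=rtit,
                gaze_shift_time_s=gaze, outcome=outcome,
                free_reward_time_s=free_reward, st_direction_deg=direction))
            trial_id += 1
    return trials


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tabulate trials with the canonical column order (absent events NaN)."""
    rows = []
    for tr in trials:
        rows.append({c: getattr(tr, c) for c in TRIAL_COLUMNS})
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    for col in ("fp_onset_s", "st_onset_s", "reward_time_s", "free_reward_time_s"):
        df[col] = df[col].astype(float)
    return df


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    out = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in TRIAL_COLUMNS}
        for c in ("fp_onset_s", "st_onset_s", "reward_time_s", "free_reward_time_s"):
            if pd.isna(kwargs[c]):
                kwargs[c] = None
        for c in ("trial_id", "block_id", "index_in_block"):
            kwargs[c] = int(kwargs[c])
        out.append(TrialRecord(**kwargs))
    return out


def event_times(trials: pd.DataFrame, event: str) -> pd.Series:
    """Per-trial time of an alignment event (NaN where absent).

    ``"stim"`` resolves to the initial stimulus: the FP when the task variant
    presents one, otherwise the FT.
    """
    if event == "stim":
        fp = trials["fp_onset_s"]
        return fp.where(fp.notna(), trials["ft_onset_s"])
    try:
        col = EVENT_COLUMNS[event]
    except KeyError:
        raise ValueError(f"unknown alignment event {event!r}") from None
    return trials[col]
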