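"""Per-neuron classification and modulation indices.

A neuron is "tonic excitatory" or "tonic suppressive" when its per-trial
firing rate in the post-fixation period (0-600 ms after the initial-stimulus
onset) differs significantly (two-sided Wilcoxon rank-sum, p < 0.05) from the
pre-fixation period (600 ms before the onset), in the corresponding
direction; otherwise it is unmodulated.  The fixation-period response is the
ROC value between the same two windows.  Reward modulation compares large vs
small reward trials in the cue (post-FT) and outcome (post-reward) periods;
behavioral modulation compares short- vs long-RTit trials (per-neuron median
split) in the pre-fixation window.  Modulation onset is read off the
normalized activity trace with a two-standard-deviation rule.

All analyses use correctly performed trials, excluding the first three
trials of each block (adaptation to the contingency switch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .roc import (ConditionComparison, NormalizedActivityTrace,
                  compare_conditions, normalized_activity_trace, rank_sum_p,
                  roc_value)
from .spike_metrics import SpikeTrainSet, event_window_rates

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Event-relative analysis windows (seconds, half-open)."""

    pre_fixation: tuple[float, float] = (-0.6, 0.0)  # re initial stimulus
    post_fixation: tuple[float, float] = (0.0, 0.6)  # re initial stimulus
    cue: tuple[float, float] = (0.0, 0.6)  # re FT onset
    outcome: tuple[float, float] = (0.0, 0.6)  # re reward delivery

    def __post_init__(self) -> None:
        for name in ("pre_fixation", "post_fixation", "cue", "outcome"):
            a, b = getattr(self, name)
            if b <= a:
                raise ValueError(f"{name}: width must be positive")


@dataclass(frozen=True)
class OnsetResult:
    """Detected start of tonic modulation on a normalized activity trace."""

    time_s: float  # relative to the trace's alignment event
    sign: int  # +1 upward departure, -1 downward


@dataclass(frozen=True)
class RegressionResult:
    """OLS of cue-period rate on reward magnitude and FT shape indicators."""

    coef_reward: float
    p_reward: float
    coef_shape: float
    p_shape: float
    n_trials: int


@dataclass
class ModulationProfile:
    """All per-neuron indices in one row."""

    neuron_id: str
    tonic_category: str
    tonic_p: Optional[float]
    fixation_response_roc: float
    reward_mod_cue_roc: Optional[float] = None
    reward_mod_cue_p: Optional[float] = None
    reward_mod_outcome_roc: Optional[float] = None
    reward_mod_outcome_p: Optional[float] = None
    behavior_mod_roc: Optional[float] = None
    behavior_mod_p: Optional[float] = None
    rtit_median_s: Optional[float] = None
    onset_time_s: Optional[float] = None
    onset_sign: Optional[int] = None
    regression: Optional[RegressionResult] = None


def filter_trials(trials: pd.DataFrame, n_exclude: int = 3) -> pd.DataFrame:
    """Correct trials only, excluding the first ``n_exclude`` of each block."""
    keep = (trials["outcome"] == "success") & (trials["index_in_block"] > n_exclude)
    return trials.loc[keep]


def _pre_post_rates(neuron: SpikeTrainSet, trials: pd.DataFrame,
                    windows: WindowSpec) -> tuple[np.ndarray, np.ndarray]:
    pre, _ = event_window_rates(neuron, trials, "stim", windows.pre_fixation)
    post, _ = event_window_rates(neuron, trials, "stim", windows.post_fixation)
    return pre, post


def classify_tonic(neuron: SpikeTrainSet, trials: pd.DataFrame | None = None,
                   windows: WindowSpec = WindowSpec(), alpha: float = 0.05,
                   ) -> tuple[str, Optional[float]]:
    """Tonic category from the pre- vs post-fixation rank-sum test.

    Returns ``(category, p)``; with fewer than 2 analysis trials the neuron
    is reported unmodulated with an absent p-value (flagged).
    """
    if trials is None:
        trials = filter_trials(neuron.trials)
    if len(trials) < 2:
        log.warning("%s: <2 analysis trials; classified unmodulated",
                    neuron.neuron_id)
        return "unmodulated", None
    pre, post = _pre_post_rates(neuron, trials, windows)
    p = rank_sum_p(post, pre)
    if p < alpha:
        increased = np.median(post) > np.median(pre)
        if np.median(post) == np.median(pre):  # rank shift with equal medians
            increased = post.mean() > pre.mean()
        return ("tonic_excitatory" if increased else "tonic_suppressive"), p
    return "unmodulated", p


def fixation_period_response(neuron: SpikeTrainSet,
                             trials: pd.DataFrame | None = None,
                             windows: WindowSpec = WindowSpec()) -> float:
    """ROC of post- vs pre-fixation per-trial rates (>0.5 = increase)."""
    if trials is None:
        trials = filter_trials(neuron.trials)
    pre, post = _pre_post_rates(neuron, trials, windows)
    return roc_value(post, pre).roc


def reward_modulation(neuron: SpikeTrainSet, trials: pd.DataFrame,
                      period: str = "cue",
                      windows: WindowSpec = WindowSpec(),
                      ) -> Optional[ConditionComparison]:
    """Large- vs small-reward rate comparison in the cue or outcome period.

    Large-reward trials form the first sample, so roc > 0.5 is positive
    reward modulation.  Returns None (flagged) when a condition is absent.
    """
    if period == "cue":
        event, window = "ft", windows.cue
    elif period == "outcome":
        event, window = "reward", windows.outcome
    else:
        raise ValueError(f"period must be 'cue' or 'outcome', got {period!r}")
    large = trials[trials["reward_size"] == "large"]
    small = trials[trials["reward_size"] == "small"]
    if len(large) == 0 or len(small) == 0:
        log.warning("%s: a reward condition is absent", neuron.neuron_id)
        return None
    return compare_conditions(neuron, large, small, event, window)


def behavior_modulation(neuron: SpikeTrainSet, trials: pd.DataFrame,
                        windows: WindowSpec = WindowSpec(),
                        ) -> Optional[tuple[ConditionComparison, float]]:
    """Short- vs long-RTit rate comparison in the pre-fixation window.

    Trials are split at the neuron's median RTit (ties go to the long side);
    short-RTit trials form the first sample, so roc > 0.5 means higher
    anticipatory activity when the gaze shift is early.  Returns
    ``(comparison, rtit_median)`` or None when a side has < 2 trials.
    """
    rtit = trials["rtit_s"].to_numpy(dtype=float)
    if len(trials) < 4 or np.isnan(rtit).any():
        log.warning("%s: RTit split not possible", neuron.neuron_id)
        return None
    median = float(np.median(rtit))
    short = trials.loc[rtit < median]
    longs = trials.loc[rtit >= median]
    if len(short) < 2 or len(longs) < 2:
        log.warning("%s: <2 trials on one RTit side", neuron.neuron_id)
        return None
    cmp = compare_conditions(neuron, short, longs, "stim", windows.pre_fixation)
    return cmp, median


def onset_time(trace: NormalizedActivityTrace, k: int = 3, n_sd: float = 2.0,
               baseline_span: tuple[float, float] | None = None,
               ) -> Optional[OnsetResult]:
    """First sustained departure of the trace from its baseline band.

    The mean and SD of the trace are taken over ``baseline_span`` (default:
    the trace's own baseline window); scanning forward from the start of
    that span, the onset is the first time at which the trace stays outside
    ``mean +/- n_sd * SD`` for at least ``k`` consecutive bins.  ``k = 1``
    reproduces the literal single-crossing rule.

    When the trace step is finer than the sliding window, neighbouring bins
    share most of their spikes, so the raw SD over baseline bins
    underestimates the marginal bin noise; the SD is therefore estimated
    from differences between bins one full window apart (which share no
    data), falling back to the plain SD on short baselines.
    """
    if baseline_span is None:
        baseline_span = trace.baseline_window
    a, b = baseline_span
    in_base = (trace.times >= a) & (trace.times < b)
    if not in_base.any():
        raise ValueError("trace does not cover the baseline span")
    base_vals = trace.values[in_base]
    m = float(base_vals.mean())
    step_size = float(np.median(np.diff(trace.times))) if trace.times.size > 1 \
        else trace.window_s
    lag = max(1, int(round(trace.window_s / step_size)))
    if base_vals.size > lag + 2:
        s = float(np.std(base_vals[lag:] - base_vals[:-lag]) / np.sqrt(2.0))
    else:
        s = float(base_vals.std())
    start = int(np.argmax(trace.times >= a))
    dev = trace.values[start:] - m
    outside = np.abs(dev) > n_sd * s
    run, run_sign = 0, 0
    for i, out in enumerate(outside):
        sign = 1 if dev[i] > 0 else -1
        if out and (run == 0 or sign == run_sign):
            run += 1
            run_sign = sign
        elif out:  # departure flipped direction: a new run starts here
            run, run_sign = 1, sign
        else:
            run = 0
        if run >= k:
            first = i - k + 1
            return OnsetResult(float(trace.times[start + first]), run_sign)
    return None


def regress_reward_vs_shape(neuron: SpikeTrainSet, trials: pd.DataFrame,
                            windows: WindowSpec = WindowSpec(),
                            ) -> Optional[RegressionResult]:
    """OLS of per-trial cue-period rate on reward size and FT shape.

    Both predictors are 0/1 indicators (large reward = 1; first shape in
    sorted order = 1).  Because the shape-reward contingency reverses
    between blocks the two indicators decorrelate across blocks; with a
    single block (or no contingency variation) the design is collinear and
    None is returned with an explanatory log message.
    """
    rates, tids = event_window_rates(neuron, trials, "ft", windows.cue)
    sub = trials.set_index("trial_id").loc[tids]
    reward = (sub["reward_size"] == "large").to_numpy(dtype=float)
    shapes = sorted(sub["ft_shape"].unique())
    shape = (sub["ft_shape"] == shapes[0]).to_numpy(dtype=float)
    X = np.column_stack([reward, shape])
    if np.linalg.matrix_rank(sm.add_constant(X)) < 3:
        log.warning("%s: reward and shape indicators are collinear (single "
                    "contingency block?); regression withheld",
                    neuron.neuron_id)
        return None
    res = sm.OLS(rates, sm.add_constant(X)).fit()
    return RegressionResult(
        coef_reward=float(res.params[1]), p_reward=float(res.pvalues[1]),
        coef_shape=float(res.params[2]), p_shape=float(res.pvalues[2]),
        n_trials=len(rates))


def profile_neuron(neuron: SpikeTrainSet,
                   windows: WindowSpec = WindowSpec(),
                   alpha: float = 0.05,
                   trace: NormalizedActivityTrace | None = None,
                   step: float = 0.01,
                   trace_span: tuple[float, float] = (-1.0, 1.5),
                   onset_k: int = 3,
                   with_regression: bool = True) -> ModulationProfile:
    """Compute the full per-neuron :class:`ModulationProfile`.

    Trials are filtered (correct, first three of each block dropped) before
    any index is computed; onset detection uses the all-trials
    stimulus-aligned trace (computed here unless one is supplied).
    """
    analysis = filter_trials(neuron.trials)
    category, tonic_p = classify_tonic(neuron, analysis, windows, alpha)
    prof = ModulationProfile(
        neuron_id=neuron.neuron_id, tonic_category=category, tonic_p=tonic_p,
        fixation_response_roc=fixation_period_response(neuron, analysis, windows))
    rm = reward_modulation(neuron, analysis, "cue", windows)
    if rm is not None:
        prof.reward_mod_cue_roc, prof.reward_mod_cue_p = rm.roc, rm.p
    rm = reward_modulation(neuron, analysis, "outcome", windows)
    if rm is not None:
        prof.reward_mod_outcome_roc, prof.reward_mod_outcome_p = rm.roc, rm.p
    bm = behavior_modulation(neuron, analysis, windows)
    if bm is not None:
        prof.behavior_mod_roc, prof.behavior_mod_p = bm[0].roc, bm[0].p
        prof.rtit_median_s = bm[1]
    if trace is None:
        trace = normalized_activity_trace(
            neuron, analysis, "stim", span=trace_span, step=step,
            baseline_window=windows.pre_fixation)
    onset = onset_time(trace, k=onset_k)
    if onset is not None:
        prof.onset_time_s, prof.onset_sign = onset.time_s, onset.sign
    if with_regression:
        prof.regression = regress_reward_vs_shape(neuron, analysis, windows)
    return prof
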