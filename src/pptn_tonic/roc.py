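"""Tie-excluding ROC discrimination index and normalized activity traces.

The ROC value between two samples of per-trial firing rates is the
probability that a randomly chosen rate from the first sample exceeds a
randomly chosen rate from the second, with tied pairs excluded from both the
numerator and the denominator.  1 means the first condition is always
higher, 0.5 means no discrimination, 0 means the second is always higher.

The normalized activity trace of a neuron is the time series of ROC values
comparing the firing rate in a 200 ms window sliding over the trial against
the rate in a fixed 600 ms pre-fixation baseline window (just before the
initial-stimulus onset), so both task-period and intertrial activity are
expressed on a common 0-1 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .spike_metrics import SpikeTrainSet, event_window_rates
from .task import event_times

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RocResult:
    """ROC value plus the pair bookkeeping behind it."""

    roc: float
    n_a: int
    n_b: int
    n_ties: int  # number of tied (excluded) pairs


@dataclass
class NormalizedActivityTrace:
    """ROC-normalized activity versus time around an alignment event."""

    neuron_id: str
    alignment_event: str
    condition: str
    times: np.ndarray  # window centres, s relative to the event
    values: np.ndarray  # ROC vs the pre-fixation baseline, in [0, 1]
    baseline_window: tuple[float, float]
    window_s: float
    n_trials: int


def roc_value(sample_a, sample_b) -> RocResult:
    """Tie-excluding ROC value between two firing-rate samples.

    roc = #{(a, b) : a > b} / #{(a, b) : a != b}.  When every pair ties
    (e.g. two constant, equal samples) there is no informative pair and the
    non-discrimination value 0.5 is returned (logged).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    b_sorted = np.sort(b)
    n_lt = int(np.searchsorted(b_sorted, a, side="left").sum())   # pairs b < a
    n_le = int(np.searchsorted(b_sorted, a, side="right").sum())  # pairs b <= a
    n_ties = n_le - n_lt
    denom = a.size * b.size - n_ties
    if denom == 0:
        log.debug("all %d pairs tied; returning 0.5", n_ties)
        return RocResult(0.5, a.size, b.size, n_ties)
    return RocResult(n_lt / denom, a.size, b.size, n_ties)


def normalized_activity_trace(neuron: SpikeTrainSet,
                              trials: pd.DataFrame | None = None,
                              alignment_event: str = "stim",
                              span: tuple[float, float] = (-1.0, 1.5),
                              step: float = 0.01,
                              window_s: float = 0.2,
                              baseline_window: tuple[float, float] = (-0.6, 0.0),
                              condition: str = "all",
                              ) -> NormalizedActivityTrace:
    """Sliding-window ROC trace of one neuron against its pre-fixation baseline.

    For every window centre ``t`` in ``span`` (relative to
    ``alignment_event``), the per-trial rates in ``[t - w/2, t + w/2)`` are
    compared by :func:`roc_value` against the per-trial baseline rates
    (``baseline_window`` relative to the initial stimulus) of the same
    trials.  Trials lacking the alignment event are dropped and logged.
    """
    if trials is None:
        trials = neuron.trials
    ev = event_times(trials, alignment_event)
    keep = ev.notna()
    if not keep.all():
        log.debug("%s: %d trials lack event %r; dropped", neuron.neuron_id,
                  int((~keep).sum()), alignment_event)
    kept = trials.loc[keep]
    if len(kept) == 0:
        raise ValueError(f"no trial carries event {alignment_event!r}")
    baseline, _ = event_window_rates(neuron, kept, "stim", baseline_window)
    ev = ev[keep].to_numpy(dtype=float)
    tids = kept["trial_id"].to_numpy()
    times = np.round(np.arange(span[0], span[1] + step / 2, step), 9)
    half = window_s / 2.0
    rates = np.empty((len(tids), times.size))
    empty = np.empty(0)
    for i, (tid, t0) in enumerate(zip(tids, ev)):
        spk = neuron.spikes.get(tid, empty)
        lo = np.searchsorted(spk, t0 + times - half, side="left")
        hi = np.searchsorted(spk, t0 + times + half, side="left")
        rates[i] = (hi - lo) / window_s
    values = np.array([roc_value(rates[:, j], baseline).roc
                       for j in range(times.size)])
    return NormalizedActivityTrace(
        neuron_id=neuron.neuron_id, alignment_event=alignment_event,
        condition=condition, times=times, values=values,
        baseline_window=baseline_window, window_s=window_s,
        n_trials=len(tids))


@dataclass(frozen=True)
class ConditionComparison:
    """ROC + rank-sum comparison of per-trial rates between two trial sets."""

    roc: float
    p: Optional[float]  # two-sided Wilcoxon rank-sum p; None if too few trials
    n_a: int
    n_b: int


def rank_sum_p(sample_a, sample_b) -> float:
    """Two-sided Wilcoxon rank-sum p (tie-corrected normal approximation)."""
    return float(stats.mannwhitneyu(sample_a, sample_b,
                                    alternative="two-sided",
                                    method="asymptotic",
                                    use_continuity=False).pvalue)


def compare_conditions(neuron: SpikeTrainSet, trials_a: pd.DataFrame,
                       trials_b: pd.DataFrame, event: str,
                       window: tuple[float, float]) -> ConditionComparison:
    """Compare per-trial firing rates between two trial subsets.

    Rates are taken in ``window`` relative to ``event``; the first subset is
    the first ROC sample (roc > 0.5 means higher rates in ``trials_a``).
    With fewer than 2 trials on either side the p-value is withheld.
    """
    if len(trials_a) == 0 or len(trials_b) == 0:
        raise ValueError("both trial subsets must be non-empty")
    ra, _ = event_window_rates(neuron, trials_a, event, window)
    rb, _ = event_window_rates(neuron, trials_b, event, window)
    roc = roc_value(ra, rb).roc
    if ra.size < 2 or rb.size < 2:
        log.warning("%s: <2 trials in a condition; p-value withheld",
                    neuron.neuron_id)
        return ConditionComparison(roc, None, ra.size, rb.size)
    return ConditionComparison(roc, rank_sum_p(ra, rb), ra.size, rb.size)
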