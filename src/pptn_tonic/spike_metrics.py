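"""Elementary per-neuron spike-train measurements.

Windowed firing rates use the half-open convention [a, b); alignment is
``spike_time - event_time`` throughout.  The irregularity index is the median,
over spikes recorded in correct trials, of the coefficient of variation of
the five successive interspike intervals starting at each spike (windows
never span trial boundaries).  Spike duration is the time from the first
negative deflection of the mean waveform to the subsequent positive peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .task import event_times

log = logging.getLogger(__name__)


@dataclass
class SpikeTrainSet:
    """One neuron's trial-aligned spike trains plus the session trial table.

    ``spikes`` maps trial_id -> sorted spike times in seconds relative to
    trial start (same clock as the event columns of ``trials``).
    """

    neuron_id: str
    spikes: Dict[int, np.ndarray]
    trials: pd.DataFrame

    def correct_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["outcome"] == "success"]


@dataclass
class EphysProperties:
    """Electrophysiological fingerprint of one neuron."""

    neuron_id: str
    baseline_rate: float  # median pre-fixation rate, spikes/s
    irregularity_index: Optional[float]  # median CV of 5 successive ISIs
    spike_duration_ms: Optional[float]


def window_rate(spikes: np.ndarray, window: tuple[float, float]) -> float:
    """Firing rate (spikes/s) in the half-open window [a, b)."""
    a, b = window
    if b <= a:
        raise ValueError(f"empty window [{a}, {b})")
    spikes = np.asarray(spikes, dtype=float)
    lo, hi = np.searchsorted(spikes, [a, b], side="left")
    return float(hi - lo) / (b - a)


def event_window_rates(train_set: SpikeTrainSet, trials: pd.DataFrame | None,
                       event: str, window: tuple[float, float],
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial firing rates in a window relative to an alignment event.

    Returns ``(rates, trial_ids)``; trials lacking the event are dropped and
    logged.  ``trials`` defaults to the full session table.
    """
    a, b = window
    if b <= a:
        raise ValueError(f"empty window [{a}, {b})")
    if trials is None:
        trials = train_set.trials
    ev = event_times(trials, event)
    missing = ev.isna()
    if missing.any():
        log.debug("%s: dropped %d trials lacking event %r",
                  train_set.neuron_id, int(missing.sum()), event)
    kept = trials.loc[~missing]
    ev = ev[~missing].to_numpy(dtype=float)
    tids = kept["trial_id"].to_numpy()
    rates = np.empty(len(tids))
    empty = np.empty(0)
    for i, (tid, t0) in enumerate(zip(tids, ev)):
        spk = train_set.spikes.get(tid, empty)
        lo, hi = np.searchsorted(spk, [t0 + a, t0 + b], side="left")
        rates[i] = (hi - lo) / (b - a)
    return rates, tids


def spike_density(spikes: np.ndarray, kernel_sd: float,
                  grid: np.ndarray) -> np.ndarray:
    """Gaussian-kernel spike density function evaluated on ``grid`` (spikes/s).

    The trace integrates to the spike count over any interval containing all
    of the kernel mass.
    """
    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be strictly positive")
    spikes = np.asarray(spikes, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if spikes.size == 0:
        return np.zeros_like(grid)
    z = (grid[:, None] - spikes[None, :]) / kernel_sd
    dens = np.exp(-0.5 * z * z).sum(axis=1)
    return dens / (kernel_sd * np.sqrt(2.0 * np.pi))


def _window_cvs(isis: np.ndarray, width: int = 5) -> np.ndarray:
    if isis.size < width:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(isis, width)
    mean = win.mean(axis=1)
    sd = win.std(axis=1, ddof=1)
    ok = mean > 0
    return sd[ok] / mean[ok]


def irregularity_index(train_set: SpikeTrainSet,
                       correct_trials: pd.DataFrame | None = None,
                       n_isis: int = 5) -> Optional[float]:
    """Median CV of ``n_isis`` successive interspike intervals.

    For every spike that is followed by at least ``n_isis`` intervals within
    the same correct trial, the CV (sample SD / mean) of those intervals is
    computed; the index is the median over all such spikes.  Returns None
    (flagged in the log) when no spike qualifies.
    """
    if correct_trials is None:
        correct_trials = train_set.correct_trials()
    cvs = []
    for tid in correct_trials["trial_id"]:
        spk = train_set.spikes.get(tid)
        if spk is None or len(spk) < n_isis + 1:
            continue
        cvs.append(_window_cvs(np.diff(spk), n_isis))
    if not cvs:
        log.warning("%s: no spike with %d successive ISIs in correct trials",
                    train_set.neuron_id, n_isis)
        return None
    allcv = np.concatenate(cvs)
    if allcv.size == 0:
        return None
    return float(np.median(allcv))


def spike_duration(waveform: np.ndarray, sampling_rate: float,
                   smooth_sd_ms: float = 0.05) -> Optional[float]:
    """Spike duration in ms: first negative deflection to the next positive peak.

    The negative deflection is the global minimum of the waveform; the
    duration runs to the maximum of the samples after it.  The waveform is
    lightly Gaussian-smoothed (``smooth_sd_ms``, default 0.05 ms; 0 disables)
    before the extrema are located, so that sample-level recording noise does
    not displace them.  Returns None (flagged) when no positive deflection
    follows the trough.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < 2:
        return None
    if smooth_sd_ms > 0:
        from scipy.ndimage import gaussian_filter1d
        w = gaussian_filter1d(w, smooth_sd_ms * sampling_rate / 1000.0)
    i_min = int(np.argmin(w))
    tail = w[i_min + 1:]
    if tail.size == 0 or tail.max() <= 0:
        log.warning("no positive peak after the negative deflection")
        return None
    i_max = i_min + 1 + int(np.argmax(tail))
    return (i_max - i_min) / sampling_rate * 1000.0


def ephys_properties(train_set: SpikeTrainSet,
                     waveform: np.ndarray | None = None,
                     sampling_rate: float = 40_000.0,
                     pre_fixation: tuple[float, float] = (-0.6, 0.0),
                     ) -> EphysProperties:
    """Baseline rate, irregularity and spike duration for one neuron.

    The baseline rate is the median pre-fixation (600 ms before the initial
    stimulus) firing rate over correct trials.
    """
    correct = train_set.correct_trials()
    rates, _ = event_window_rates(train_set, correct, "stim", pre_fixation)
    baseline = float(np.median(rates)) if rates.size else float("nan")
    dur = (spike_duration(waveform, sampling_rate)
           if waveform is not None else None)
    return EphysProperties(
        neuron_id=train_set.neuron_id,
        baseline_rate=baseline,
        irregularity_index=irregularity_index(train_set, correct),
        spike_duration_ms=dur,
    )
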