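"""Population-level inference over per-neuron modulation indices.

Correlations between indices use Spearman's rank correlation with a
permutation test (20,000 shuffles of the pairing by default); frequency
contrasts use the Pearson chi-square test on a 2x2 table; firing-rate
contrasts between neuron groups use rank-sum tests with a Bonferroni
threshold of 0.05/6 across the six pairwise comparisons.  Heatmap rows are
sorted by the onset of tonic modulation within each category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .roc import NormalizedActivityTrace, rank_sum_p

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rho with a permutation p-value."""

    rho: Optional[float]
    p_perm: Optional[float]
    n_pairs: int
    n_shuffles: int


def _centred_ranks(x: np.ndarray) -> np.ndarray:
    r = stats.rankdata(x, method="average")
    r = r - r.mean()
    norm = np.sqrt((r * r).sum())
    return r / norm if norm > 0 else r


def spearman_perm(x, y, n_shuffles: int = 20_000, seed=None,
                  ) -> CorrelationResult:
    """Spearman rank correlation with a two-sided permutation test.

    The observed rho is the Pearson correlation of average ranks; the null
    distribution is built by shuffling ``y`` against ``x`` ``n_shuffles``
    times.  The p-value ``(1 + #{|rho_perm| >= |rho_obs|}) / (n_shuffles + 1)``
    honours the floor ``1 / (n_shuffles + 1)``.  Constant inputs have no
    rank ordering and return an absent rho (flagged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d samples")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        log.warning("constant input vector; correlation undefined")
        return CorrelationResult(None, None, x.size, n_shuffles)
    rx = _centred_ranks(x)
    ry = _centred_ranks(y)
    rho = float(rx @ ry)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(ry, (n_shuffles, 1)), axis=1)
    rho_perm = perms @ rx
    n_ge = int(np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12))
    p = (1 + n_ge) / (n_shuffles + 1)
    return CorrelationResult(rho, p, x.size, n_shuffles)


def abs_modulation(roc: float) -> float:
    """Absolute modulation strength: |ROC - 0.5|."""
    if not 0.0 <= roc <= 1.0:
        raise ValueError(f"ROC value {roc} outside [0, 1]")
    return abs(roc - 0.5)


def chi_square_2x2(counts) -> tuple[Optional[float], Optional[float]]:
    """Pearson chi-square (no continuity correction) on a 2x2 count table."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("counts must be a non-negative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        log.warning("degenerate margins; chi-square undefined")
        return None, None
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


@dataclass(frozen=True)
class RateComparison:
    group_a: str
    group_b: str
    median_a: float
    median_b: float
    p: float
    significant: bool  # at the Bonferroni-corrected level


def group_rate_comparison(rates: Dict[str, np.ndarray], alpha: float = 0.05,
                          ) -> list[RateComparison]:
    """All pairwise rank-sum tests between the four group/period rate samples.

    ``rates`` maps sample names (conventionally ``excitatory_pre``,
    ``excitatory_post``, ``suppressive_pre``, ``suppressive_post``) to
    per-neuron rate vectors; each of the 6 pairs is flagged significant iff
    p < alpha / 6 (Bonferroni).  Comparisons touching an empty group are
    omitted.
    """
    names = list(rates)
    if len(names) != 4:
        raise ValueError("expected exactly four rate samples")
    thr = alpha / 6.0
    out = []
    for i in range(4):
        for j in range(i + 1, 4):
            a, b = np.asarray(rates[names[i]]), np.asarray(rates[names[j]])
            if a.size == 0 or b.size == 0:
                log.warning("empty group; %s vs %s omitted", names[i], names[j])
                continue
            p = rank_sum_p(a, b)
            out.append(RateComparison(names[i], names[j],
                                      float(np.median(a)), float(np.median(b)),
                                      p, p < thr))
    return out


def sort_by_onset(onsets: Sequence[Optional[float]],
                  neuron_ids: Sequence | None = None) -> list[int]:
    """Indices ordering neurons by ascending onset time.

    Absent onsets go last; ties break by neuron id (stable).
    """
    n = len(onsets)
    ids = list(neuron_ids) if neuron_ids is not None else list(range(n))
    key = [(0, onsets[i], ids[i]) if onsets[i] is not None else (1, 0.0, ids[i])
           for i in range(n)]
    return sorted(range(n), key=lambda i: key[i])


def population_average(traces: Sequence[NormalizedActivityTrace],
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise unweighted mean of per-neuron ROC traces on a common grid."""
    if not traces:
        raise ValueError("no traces to average")
    t0 = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
            raise ValueError("traces are not on a common time grid")
    values = np.mean([tr.values for tr in traces], axis=0)
    return t0.copy(), values


@dataclass
class PopulationSummary:
    """Counts, correlations and group contrasts over one analyzed population."""

    n_neurons: int
    category_counts: Dict[str, int]
    pre_onset_counts: Dict[str, int]  # onsets before the initial stimulus
    pre_onset_chi2: tuple[Optional[float], Optional[float]]
    correlations: Dict[str, CorrelationResult]
    rate_comparisons: list[RateComparison]

    def __post_init__(self) -> None:
        if sum(self.category_counts.values()) != self.n_neurons:
            raise ValueError("category counts must sum to the population size")


def summarize_population(profiles: pd.DataFrame,
                         rates: Dict[str, np.ndarray] | None = None,
                         n_shuffles: int = 20_000, seed=None,
                         ) -> PopulationSummary:
    """Population summary from a per-neuron profile table.

    ``profiles`` is the frame written by the pipeline (one row per neuron
    with the ModulationProfile columns).  Correlations are computed over all
    neurons with both indices present, including unmodulated ones.
    """
    rng = np.random.default_rng(seed)
    cats = ("tonic_excitatory", "tonic_suppressive", "unmodulated")
    counts = {c: int((profiles["tonic_category"] == c).sum()) for c in cats}
    pre_onset = {}
    for c in cats[:2]:
        sub = profiles[profiles["tonic_category"] == c]
        pre_onset[c] = int((sub["onset_time_s"] < 0).sum())
    table = [[pre_onset["tonic_excitatory"],
              counts["tonic_excitatory"] - pre_onset["tonic_excitatory"]],
             [pre_onset["tonic_suppressive"],
              counts["tonic_suppressive"] - pre_onset["tonic_suppressive"]]]
    try:
        chi2 = chi_square_2x2(table)
    except ValueError:
        chi2 = (None, None)

    def corr(xcol: str, ycol: str, absolute: bool = False) -> CorrelationResult:
        sub = profiles[[xcol, ycol]].dropna()
        if len(sub) < 3:
            return CorrelationResult(None, None, len(sub), n_shuffles)
        x = sub[xcol].to_numpy(dtype=float)
        y = sub[ycol].to_numpy(dtype=float)
        if absolute:
            x, y = np.abs(x - 0.5), np.abs(y - 0.5)
        return spearman_perm(x, y, n_shuffles=n_shuffles,
                             seed=rng.integers(2**31))

    correlations = {
        "fixation_x_reward_cue": corr("fixation_response_roc",
                                      "reward_mod_cue_roc"),
        "fixation_x_reward_outcome": corr("fixation_response_roc",
                                          "reward_mod_outcome_roc"),
        "fixation_x_behavior": corr("fixation_response_roc",
                                    "behavior_mod_roc"),
        "reward_cue_x_behavior": corr("reward_mod_cue_roc",
                                      "behavior_mod_roc"),
        "abs_fixation_x_reward_cue": corr("fixation_response_roc",
                                          "reward_mod_cue_roc", absolute=True),
        "abs_fixation_x_behavior": corr("fixation_response_roc",
                                        "behavior_mod_roc", absolute=True),
    }
    comparisons = group_rate_comparison(rates) if rates else []
    return PopulationSummary(
        n_neurons=len(profiles), category_counts=counts,
        pre_onset_counts=pre_onset, pre_onset_chi2=chi2,
        correlations=correlations, rate_comparisons=comparisons)
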