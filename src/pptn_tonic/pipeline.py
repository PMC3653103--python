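"""End-to-end orchestration: generate -> measure -> classify -> summarize.

A run is fully determined by its :class:`RunConfig` (including the seed); the
manifest written alongside the outputs records the configuration hash,
package versions and seed needed to reproduce every file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .io import read_population, write_population
from .modulation import ModulationProfile, WindowSpec, filter_trials, profile_neuron
from .neurons import (DEFAULT_PROPORTIONS, NeuronRecording, generate_population,
                      split_by_proportions)
from .population import PopulationSummary, population_average, sort_by_onset, \
    summarize_population
from .roc import normalized_activity_trace
from .spike_metrics import SpikeTrainSet, ephys_properties, event_window_rates
from .task import TRIAL_COLUMNS, TaskConfig, event_times

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int
    outdir: str
    data_dir: Optional[str] = None  # read this bundle instead of simulating
    n_neurons: int = 40
    proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS
    reward_coupling: str = "matched"
    task: TaskConfig = field(default_factory=TaskConfig)
    windows: WindowSpec = field(default_factory=WindowSpec)
    trace_span: tuple[float, float] = (-1.0, 1.5)
    trace_step: float = 0.01
    onset_k: int = 3
    n_shuffles: int = 20_000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "task" in data:
            data["task"] = TaskConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in data["task"].items()})
        if "windows" in data:
            data["windows"] = WindowSpec(**{
                k: tuple(v) for k, v in data["windows"].items()})
        for k in ("proportions", "trace_span"):
            if k in data:
                data[k] = tuple(data[k])
        return cls(**data)


@dataclass
class ValidationReport:
    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_inputs(recordings: Sequence[NeuronRecording]) -> ValidationReport:
    """Schema and consistency checks on a population bundle (report-only)."""
    rep = ValidationReport()
    for rec in recordings:
        missing = set(TRIAL_COLUMNS) - set(rec.trials.columns)
        if missing:
            rep.fatal.append(f"{rec.neuron_id}: missing columns {sorted(missing)}")
            continue
        t = rec.trials
        for _, row in t.iterrows():
            ev = [row["fp_onset_s"], row["ft_onset_s"], row["st_onset_s"],
                  row["reward_time_s"]]
            ev = [x for x in ev if pd.notna(x)]
            if any(b <= a for a, b in zip(ev, ev[1:])):
                rep.fatal.append(
                    f"{rec.neuron_id} trial {int(row['trial_id'])}: "
                    "event times not strictly increasing")
        if t["trial_id"].duplicated().any():
            rep.fatal.append(f"{rec.neuron_id}: duplicated trial_id")
        for blk, grp in t.groupby("block_id"):
            idx = grp["index_in_block"].to_numpy()
            if (np.diff(idx) != 1).any() or idx[0] != 1:
                rep.warnings.append(
                    f"{rec.neuron_id}: block {blk} indices not consecutive")
        tids = set(t["trial_id"].astype(int))
        for tid, spk in rec.spikes.items():
            if tid not in tids:
                rep.fatal.append(f"{rec.neuron_id}: spikes for unknown trial {tid}")
            if np.any(np.diff(spk) < 0):
                rep.fatal.append(f"{rec.neuron_id} trial {tid}: unsorted spikes")
            elif np.any(np.asarray(spk) < 0):
                rep.fatal.append(f"{rec.neuron_id} trial {tid}: negative spike time")
    return rep


def _profiles_frame(profiles: Sequence[ModulationProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        d = dataclasses.asdict(p)
        reg = d.pop("regression")
        if reg is not None:
            d.update({f"regression_{k}": v for k, v in reg.items()})
        rows.append(d)
    return pd.DataFrame(rows)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> PopulationSummary:
    """Run the full analysis; writes all outputs under ``config.outdir``.

    Outputs: the simulated data bundle (``data/``), per-neuron
    ``profiles.csv`` and ``ephys.csv``, long-format ``traces.csv``, the
    onset-sorted ``heatmap.csv``, per-category mean traces, a JSON
    ``summary.json``, a plain-text ``report.txt`` and ``manifest.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.data_dir is not None:
        recordings = read_population(config.data_dir)
        truth = None
    else:
        n_cat = split_by_proportions(config.n_neurons, config.proportions)
        population = generate_population(
            n_cat, config.task, config.seed,
            reward_coupling=config.reward_coupling)
        write_population(population, outdir / "data")
        recordings = [rec for rec, _ in population]
        truth = {rec.neuron_id: prof.category for rec, prof in population}
    report = validate_inputs(recordings)
    for msg in report.warnings:
        log.warning("validation: %s", msg)
    if not report.ok:
        raise ValueError("input validation failed: " + "; ".join(report.fatal))

    profiles, traces, ephys = [], {}, []
    for rec in recordings:
        analysis = filter_trials(rec.trials)
        log.info("%s: %d/%d trials retained after filtering", rec.neuron_id,
                 len(analysis), len(rec.trials))
        trace = normalized_activity_trace(
            rec, analysis, "stim", span=config.trace_span,
            step=config.trace_step, baseline_window=config.windows.pre_fixation)
        traces[rec.neuron_id] = trace
        profiles.append(profile_neuron(
            rec, config.windows, config.alpha, trace=trace,
            onset_k=config.onset_k))
        wav = getattr(rec, "waveform", None)
        ephys.append(ephys_properties(rec, wav,
                                      pre_fixation=config.windows.pre_fixation))

    pframe = _profiles_frame(profiles)
    if truth is not None:
        pframe["true_category"] = pframe["neuron_id"].map(truth)
    pframe.to_csv(outdir / "profiles.csv", index=False)
    pd.DataFrame([dataclasses.asdict(e) for e in ephys]) \
        .to_csv(outdir / "ephys.csv", index=False)

    long_rows = []
    for nid, tr in traces.items():
        for t, v in zip(tr.times, tr.values):
            long_rows.append((nid, tr.alignment_event, tr.condition, t, v))
    pd.DataFrame(long_rows, columns=["neuron_id", "alignment_event",
                                     "condition", "time_s", "roc"]) \
        .to_csv(outdir / "traces.csv", index=False)

    # heatmap: within-category onset order, one row of ROC values per neuron
    heat_rows, order_ids = [], []
    for cat in ("tonic_excitatory", "unmodulated", "tonic_suppressive"):
        sub = pframe[pframe["tonic_category"] == cat]
        onsets = [None if pd.isna(t) else float(t)
                  for t in sub["onset_time_s"]]
        ids = sub["neuron_id"].tolist()
        for i in sort_by_onset(onsets, ids):
            order_ids.append(ids[i])
    grid = traces[order_ids[0]].times if order_ids else np.empty(0)
    for nid in order_ids:
        heat_rows.append([nid] + list(traces[nid].values))
    pd.DataFrame(heat_rows, columns=["neuron_id"] + [f"{t:.3f}" for t in grid]) \
        .to_csv(outdir / "heatmap.csv", index=False)

    mean_rows = []
    for cat in ("tonic_excitatory", "tonic_suppressive"):
        ids = pframe.loc[pframe["tonic_category"] == cat, "neuron_id"]
        cat_traces = [traces[nid] for nid in ids]
        if cat_traces:
            t, v = population_average(cat_traces)
            mean_rows += [(cat, ti, vi) for ti, vi in zip(t, v)]
    pd.DataFrame(mean_rows, columns=["category", "time_s", "mean_roc"]) \
        .to_csv(outdir / "mean_traces.csv", index=False)

    rates: Dict[str, np.ndarray] = {}
    for cat, tag in (("tonic_excitatory", "excitatory"),
                     ("tonic_suppressive", "suppressive")):
        ids = set(pframe.loc[pframe["tonic_category"] == cat, "neuron_id"])
        pre, post = [], []
        for rec in recordings:
            if rec.neuron_id not in ids:
                continue
            analysis = filter_trials(rec.trials)
            r, _ = event_window_rates(rec, analysis, "stim",
                                      config.windows.pre_fixation)
            pre.append(float(np.median(r)))
            r, _ = event_window_rates(rec, analysis, "stim",
                                      config.windows.post_fixation)
            post.append(float(np.median(r)))
        rates[f"{tag}_pre"] = np.asarray(pre)
        rates[f"{tag}_post"] = np.asarray(post)

    summary = summarize_population(pframe, rates,
                                   n_shuffles=config.n_shuffles,
                                   seed=config.seed)
    (outdir / "summary.json").write_text(json.dumps(
        dataclasses.asdict(summary), indent=1, default=float))
    (outdir / "report.txt").write_text(render_report(summary, config))
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {"pptn_tonic": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     default=str))
    return summary


def render_report(summary: PopulationSummary, config: RunConfig) -> str:
    """Plain-text mirror of the population-level quantities."""
    lines = [
        "Tonic activity analysis summary",
        "===============================",
        f"neurons analyzed: {summary.n_neurons}",
    ]
    for cat, n in summary.category_counts.items():
        pct = 100.0 * n / summary.n_neurons if summary.n_neurons else 0.0
        lines.append(f"  {cat}: {n} ({pct:.0f}%)")
    lines.append("pre-stimulus onsets (onset before the initial stimulus):")
    for cat, n in summary.pre_onset_counts.items():
        tot = summary.category_counts.get(cat, 0)
        pct = 100.0 * n / tot if tot else float("nan")
        lines.append(f"  {cat}: {n}/{tot} ({pct:.0f}%)")
    stat, p = summary.pre_onset_chi2
    if stat is not None:
        lines.append(f"  chi-square = {stat:.2f}, p = {p:.4f}")
    lines.append(f"correlations ({config.n_shuffles} shuffles):")
    for name, c in summary.correlations.items():
        if c.rho is None:
            lines.append(f"  {name}: undefined (n = {c.n_pairs})")
        else:
            lines.append(f"  {name}: rho = {c.rho:.3f}, p = {c.p_perm:.4g} "
                         f"(n = {c.n_pairs})")
    if summary.rate_comparisons:
        lines.append("group firing-rate comparisons (Bonferroni 0.05/6):")
        for rc in summary.rate_comparisons:
            flag = "*" if rc.significant else " "
            lines.append(f"  {rc.group_a} (median {rc.median_a:.1f}) vs "
                         f"{rc.group_b} (median {rc.median_b:.1f}): "
                         f"p = {rc.p:.4g}{flag}")
    lines.append(f"seed: {config.seed}")
    return "\n".join(lines) + "\n"
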