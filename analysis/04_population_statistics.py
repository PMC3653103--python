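#!/usr/bin/env python
"""Population-level statistics over the per-neuron modulation indices.

Correlates the fixation-period response with the reward- and behavior-
modulation indices (Spearman rho, 20,000-shuffle permutation test), contrasts
the frequency of pre-stimulus onsets between tonic excitatory and suppressive
neurons (chi-square), compares group firing rates (rank-sum, Bonferroni
0.05/6), and writes results/summary.json plus per-category mean traces.
"""

import dataclasses
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from pptn_tonic.io import read_population
from pptn_tonic.modulation import filter_trials
from pptn_tonic.population import summarize_population
from pptn_tonic.spike_metrics import event_window_rates

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "analysis" / "data"
OUT = ROOT / "results"
BULKY = ROOT / "scratch" / "analysis"
SEED = 404
N_SHUFFLES = 20_000


def main() -> None:
    profiles = pd.read_csv(OUT / "profiles.csv")
    recs = {r.neuron_id: r for r in read_population(DATA)}
    rates = {}
    for cat, tag in (("tonic_excitatory", "excitatory"),
                     ("tonic_suppressive", "suppressive")):
        ids = profiles.loc[profiles["tonic_category"] == cat, "neuron_id"]
        pre, post = [], []
        for nid in ids:
            analysis = filter_trials(recs[nid].trials)
            r, _ = event_window_rates(recs[nid], analysis, "stim", (-0.6, 0.0))
            pre.append(float(np.median(r)))
            r, _ = event_window_rates(recs[nid], analysis, "stim", (0.0, 0.6))
            post.append(float(np.median(r)))
        rates[f"{tag}_pre"], rates[f"{tag}_post"] = np.array(pre), np.array(post)

    summary = summarize_population(profiles, rates, n_shuffles=N_SHUFFLES,
                                   seed=SEED)
    (OUT / "summary.json").write_text(
        json.dumps(dataclasses.asdict(summary), indent=1, default=float))

    traces = pd.read_csv(BULKY / "traces.csv")
    cat_of = profiles.set_index("neuron_id")["tonic_category"]
    traces["category"] = traces["neuron_id"].map(cat_of)
    mean = (traces[traces["category"] != "unmodulated"]
            .groupby(["category", "time_s"])["roc"].mean().reset_index())
    mean.to_csv(OUT / "mean_traces.csv", index=False)

    print(f"population of {summary.n_neurons} neurons")
    for cat, n in summary.category_counts.items():
        print(f"  {cat}: {n} ({100 * n / summary.n_neurons:.0f}%)")
    print("pre-stimulus onset counts:", summary.pre_onset_counts,
          "chi-square p =", None if summary.pre_onset_chi2[1] is None
          else round(summary.pre_onset_chi2[1], 4))
    for name, c in summary.correlations.items():
        if c.rho is not None:
            print(f"  {name}: rho = {c.rho:+.3f}, permutation p = {c.p_perm:.4g}")
    for rc in summary.rate_comparisons:
        mark = " *" if rc.significant else ""
        print(f"  {rc.group_a} vs {rc.group_b}: medians "
              f"{rc.median_a:.1f} / {rc.median_b:.1f} sp/s, p = {rc.p:.3g}{mark}")
    print(f"-> {OUT / 'summary.json'}")


if __name__ == "__main__":
    sys.exit(main())
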