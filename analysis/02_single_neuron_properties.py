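#!/usr/bin/env python
"""Electrophysiological fingerprints of the simulated neurons.

Reads the bundle written by 01_simulate_population.py and measures, per
neuron, the pre-fixation baseline firing rate, the spiking-irregularity
index (median CV of five successive interspike intervals in correct trials)
and the spike duration from the waveform; writes results/ephys.csv and
prints per-category medians.
"""

import dataclasses
import sys
from pathlib import Path

import pandas as pd

from pptn_tonic.io import read_ground_truth, read_population
from pptn_tonic.spike_metrics import ephys_properties

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "analysis" / "data"
OUT = ROOT / "results"


def main() -> None:
    recs = read_population(DATA)
    truth = read_ground_truth(DATA / "ground_truth.json")
    rows = []
    for rec in recs:
        props = ephys_properties(rec, rec.waveform, rec.sampling_rate)
        row = dataclasses.asdict(props)
        row["true_category"] = truth[rec.neuron_id].category
        rows.append(row)
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "ephys.csv", index=False)
    print(f"measured {len(df)} neurons -> {OUT / 'ephys.csv'}")
    med = df.groupby("true_category")[
        ["baseline_rate", "irregularity_index", "spike_duration_ms"]].median()
    print("\nper-category medians:")
    print(med.round(2).to_string())


if __name__ == "__main__":
    sys.exit(main())
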