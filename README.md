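# pptn-tonic

Trial-aligned spike-train analysis of **tonic reward-prediction activity**,
built around the measurement chain used for pedunculopontine tegmental
nucleus (PPTN) neurons recorded during a reward-biased visually guided
saccade task — together with a synthetic-data generator that emulates the
task, so every statistic can be validated against known ground truth.

During the task, the shape of a central fixation target (FT) cues whether a
correct saccade earns a large (3-drop) or small (1-drop) juice reward, with
the shape→reward contingency reversing every 20–30 trials. Many PPTN
neurons raise ("tonic excitatory") or lower ("tonic suppressive") their
sustained firing from around task start until reward delivery, and the
direction of that tonic change predicts the sign of their reward-cue and
anticipatory-behavior modulation. The package implements the statistics
behind those observations:

- **Tie-excluding ROC index** between two samples of per-trial firing rates
  `r_i`: `ROC = #{(a,b): a > b} / #{(a,b): a ≠ b}` — 1 when the first
  condition is always higher, 0.5 for no discrimination, 0 when always lower.
- **Normalized activity trace**: ROC of a 200 ms sliding window versus the
  600 ms pre-stimulus baseline, per alignment event.
- **Tonic classification**: two-sided Wilcoxon rank-sum (p < 0.05) on
  pre- vs post-stimulus rates; **fixation-period response** = the ROC of the
  same windows.
- **Reward modulation** (large vs small reward; cue and outcome windows),
  **behavioral modulation** (short vs long reaction-time-to-fixate, median
  split), **onset detection** (first sustained departure beyond 2 SD of the
  baseline trace), **multiple regression** of cue-period rate on reward
  magnitude vs FT shape.
- **Population statistics**: Spearman correlations with 20,000-shuffle
  permutation tests, chi-square frequency contrasts, rank-sum rate contrasts
  at a Bonferroni 0.05/6 level, onset-sorted heatmaps and population-average
  traces.
- **Electrophysiological indices**: baseline rate, spiking irregularity
  (median CV of five successive interspike intervals), spike duration from
  the waveform trough to the following peak.

See `docs/methods.md` for the model, conventions and numerical choices.

## Worked example

```python
import numpy as np
from pptn_tonic import (TaskConfig, NeuronProfile, generate_trial_sequence,
                        generate_spike_train, SpikeTrainSet, filter_trials,
                        classify_tonic, fixation_period_response,
                        reward_modulation)
from pptn_tonic.task import trials_to_frame

# one tonic excitatory neuron with positive reward modulation
profile = NeuronProfile("tonic_excitatory", baseline_rate=12.0,
                        modulation_depth=12.0, reward_mod_sign=+1,
                        reward_mod_depth=6.0)
trials = generate_trial_sequence(TaskConfig(n_blocks=6), seed=1)
rng = np.random.default_rng(2)
neuron = SpikeTrainSet("demo",
                       {t.trial_id: generate_spike_train(profile, t, rng)
                        for t in trials},
                       trials_to_frame(trials))

analysis = filter_trials(neuron.trials)
category, p = classify_tonic(neuron, analysis)
fix = fixation_period_response(neuron, analysis)
cue = reward_modulation(neuron, analysis, "cue")
print(category, f"p={p:.2g}", f"fixation ROC={fix:.2f}",
      f"cue ROC={cue.roc:.2f} (p={cue.p:.2g})")
```

prints

```
tonic_excitatory p=6.3e-29 fixation ROC=0.93 cue ROC=0.94 (p=3.1e-16)
```

i.e. the neuron is recovered as tonic excitatory (rank-sum p ≈ 10⁻²⁹), its
post-stimulus rate exceeds a random baseline rate 93% of the time, and its
cue-period rate is higher on large-reward trials (ROC 0.94 > 0.5, positive
reward modulation).

The full analysis is organised as numbered drivers over the library:

```bash
python analysis/01_simulate_population.py   # 60-neuron synthetic population
python analysis/02_single_neuron_properties.py
python analysis/03_classify_and_trace.py
python analysis/04_population_statistics.py
```

which write small derived tables (`profiles.csv`, `ephys.csv`,
`summary.json`, `mean_traces.csv`) under `results/` and the bulky raw bundle
and per-bin traces under `scratch/`. The same chain is available as a CLI
(`pptn-tonic simulate / analyze / report`) for custom configurations.

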