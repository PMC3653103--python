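"""Trial filtering, tonic classification, modulation indices, onset detection."""

import numpy as np
import pandas as pd
import pytest

from conftest import build_trials_frame, poisson_train
from pptn_tonic.modulation import (WindowSpec, behavior_modulation,
                                   classify_tonic, filter_trials,
                                   fixation_period_response, onset_time,
                                   profile_neuron, regress_reward_vs_shape,
                                   reward_modulation)
from pptn_tonic.neurons import NeuronProfile, generate_spike_train
from pptn_tonic.roc import NormalizedActivityTrace
from pptn_tonic.spike_metrics import SpikeTrainSet
from pptn_tonic.task import TaskConfig, frame_to_trials, generate_trial_sequence, \
    trials_to_frame


def simulate_neuron(profile, n_blocks=5, seed=0, p_error=0.0, **task_kw):
    """A full synthetic session for one neuron profile."""
    cfg = TaskConfig(n_blocks=n_blocks, p_error=p_error, **task_kw)
    trials = generate_trial_sequence(cfg, seed)
    rng = np.random.default_rng(seed + 10_000)
    spikes = {tr.trial_id: generate_spike_train(profile, tr, rng)
              for tr in trials}
    return SpikeTrainSet("n0", spikes, trials_to_frame(trials))


class TestFilterTrials:
    def test_block_of_25_correct_trials_keeps_22(self):
        df = build_trials_frame(25)
        df["block_id"] = 0
        df["index_in_block"] = np.arange(1, 26)
        assert len(filter_trials(df)) == 22

    def test_boundary_indices(self):
        df = build_trials_frame(6)
        df["index_in_block"] = [1, 2, 3, 4, 5, 6]
        kept = filter_trials(df)["index_in_block"].tolist()
        assert kept == [4, 5, 6]

    def test_all_error_block_drops_everything(self):
        df = build_trials_frame(10)
        df["outcome"] = "fixation_break"
        assert len(filter_trials(df)) == 0


class TestClassifyTonic:
    def test_excitatory_neuron_recovered(self):
        p = NeuronProfile("tonic_excitatory", 10.0, modulation_depth=10.0)
        ts = simulate_neuron(p, seed=1)
        cat, pval = classify_tonic(ts)
        assert cat == "tonic_excitatory"
        assert pval < 0.05

    def test_suppressive_neuron_is_mirror_case(self):
        p = NeuronProfile("tonic_suppressive", 10.0, modulation_depth=10.0)
        ts = simulate_neuron(p, seed=1)
        cat, pval = classify_tonic(ts)
        assert cat == "tonic_suppressive"
        assert pval < 0.05

    def test_insufficient_trials_flagged_unmodulated(self):
        p = NeuronProfile("unmodulated", 10.0)
        ts = simulate_neuron(p, n_blocks=1, seed=2)
        ts.trials["outcome"] = "fixation_break"
        cat, pval = classify_tonic(ts)
        assert cat == "unmodulated"
        assert pval is None

    def test_agrees_in_sign_with_fixation_response(self):
        for seed, cat_true in [(3, "tonic_excitatory"), (4, "tonic_suppressive")]:
            p = NeuronProfile(cat_true, 12.0, modulation_depth=12.0)
            ts = simulate_neuron(p, seed=seed)
            trials = filter_trials(ts.trials)
            cat, _ = classify_tonic(ts, trials)
            roc = fixation_period_response(ts, trials)
            if cat == "tonic_excitatory":
                assert roc >= 0.5
            elif cat == "tonic_suppressive":
                assert roc <= 0.5


class TestFixationResponse:
    def test_fully_separated_counts_give_one(self):
        n = 20
        trials = build_trials_frame(n)
        # 2 baseline spikes, 8 post-stimulus spikes per trial
        spikes = {i: np.sort(np.concatenate([
            [1.0, 1.2], 1.55 + np.arange(8) * 0.05])) for i in range(n)}
        ts = SpikeTrainSet("n0", spikes, trials)
        assert fixation_period_response(ts, trials) == 1.0

    def test_stationary_neuron_near_half(self):
        rng = np.random.default_rng(0)
        trials = build_trials_frame(150)
        spikes = {i: poisson_train(rng, 12.0, 0.0, 3.0) for i in range(150)}
        ts = SpikeTrainSet("n0", spikes, trials)
        assert abs(fixation_period_response(ts, trials) - 0.5) < 0.1


class TestRewardModulation:
    def test_injected_positive_cue_modulation_detected(self):
        p = NeuronProfile("tonic_excitatory", 20.0, modulation_depth=20.0,
                          reward_mod_sign=1, reward_mod_depth=10.0)
        ts = simulate_neuron(p, n_blocks=8, seed=6)
        trials = filter_trials(ts.trials)
        cue = reward_modulation(ts, trials, "cue")
        assert cue.roc > 0.5
        assert cue.p < 0.05

    def test_outcome_period_is_null_by_construction(self):
        p = NeuronProfile("tonic_excitatory", 20.0, modulation_depth=20.0,
                          reward_mod_sign=1, reward_mod_depth=10.0)
        ts = simulate_neuron(p, n_blocks=8, seed=6)
        out = reward_modulation(ts, filter_trials(ts.trials), "outcome")
        assert abs(out.roc - 0.5) < 0.15

    def test_label_swap_mirrors_roc(self):
        p = NeuronProfile("tonic_excitatory", 15.0, modulation_depth=15.0,
                          reward_mod_sign=1, reward_mod_depth=7.0)
        ts = simulate_neuron(p, seed=7)
        trials = filter_trials(ts.trials)
        direct = reward_modulation(ts, trials, "cue")
        swapped = trials.assign(reward_size=trials["reward_size"].map(
            {"large": "small", "small": "large"}))
        mirrored = reward_modulation(ts, swapped, "cue")
        assert direct.roc + mirrored.roc == pytest.approx(1.0)

    def test_missing_condition_flagged(self):
        p = NeuronProfile("unmodulated", 10.0)
        ts = simulate_neuron(p, seed=8)
        trials = filter_trials(ts.trials)
        only_large = trials[trials["reward_size"] == "large"]
        assert reward_modulation(ts, only_large, "cue") is None


class TestBehaviorModulation:
    def test_gaze_locked_excitatory_neuron_positive(self):
        p = NeuronProfile("tonic_excitatory", 15.0, modulation_depth=15.0,
                          behavior_coupled=True, onset_lead_s=0.05)
        ts = simulate_neuron(p, n_blocks=8, seed=9)
        res = behavior_modulation(ts, filter_trials(ts.trials))
        cmp, median = res
        assert cmp.roc > 0.5
        assert cmp.p < 0.05
        assert -1.0 < median < 1.0

    def test_stimulus_locked_neuron_is_null(self):
        p = NeuronProfile("tonic_excitatory", 15.0, modulation_depth=15.0,
                          behavior_coupled=False, onset_lead_s=0.0)
        ts = simulate_neuron(p, n_blocks=8, seed=10)
        cmp, _ = behavior_modulation(ts, filter_trials(ts.trials))
        assert abs(cmp.roc - 0.5) < 0.12

    def test_gaze_locked_suppressive_neuron_negative(self):
        p = NeuronProfile("tonic_suppressive", 15.0, modulation_depth=15.0,
                          behavior_coupled=True, onset_lead_s=0.05)
        ts = simulate_neuron(p, n_blocks=8, seed=11)
        cmp, _ = behavior_modulation(ts, filter_trials(ts.trials))
        assert cmp.roc < 0.5

    def test_median_split_sends_ties_to_long_side(self):
        rtit = np.array([0.1] * 6 + [-0.2] * 4)
        trials = build_trials_frame(10, rtit=rtit)
        rng = np.random.default_rng(1)
        ts = SpikeTrainSet("n0", {i: poisson_train(rng, 10, 0, 3)
                                  for i in range(10)}, trials)
        cmp, median = behavior_modulation(ts, trials)
        assert median == pytest.approx(0.1)
        assert cmp.n_a == 4  # short side: strictly below the median
        assert cmp.n_b == 6  # ties joined the long side


def _trace(values, step=0.01, start=-0.8):
    values = np.asarray(values, dtype=float)
    times = start + np.arange(values.size) * step
    return NormalizedActivityTrace("n0", "stim", "all", times, values,
                                   baseline_window=(-0.6, 0.0), window_s=0.2,
                                   n_trials=100)


class TestOnsetTime:
    def _step_trace(self, onset, high, noise_sd=0.01, seed=0):
        rng = np.random.default_rng(seed)
        times = -0.8 + np.arange(160) * 0.01
        vals = np.where(times < onset, 0.5, high) + rng.normal(0, noise_sd, 160)
        return _trace(vals)

    # baseline statistics are taken over a span the step does not reach
    BASE = (-0.8, -0.3)

    def test_step_up_detected_at_step_time(self):
        res = onset_time(self._step_trace(-0.2, 0.9), baseline_span=self.BASE)
        assert res.sign == 1
        assert res.time_s == pytest.approx(-0.2, abs=0.01 + 1e-9)

    def test_step_down_mirrors_with_negative_sign(self):
        res = onset_time(self._step_trace(-0.2, 0.1), baseline_span=self.BASE)
        assert res.sign == -1
        assert res.time_s == pytest.approx(-0.2, abs=0.01 + 1e-9)

    def test_flat_trace_has_no_onset(self):
        assert onset_time(self._step_trace(10.0, 0.9),
                          baseline_span=self.BASE) is None

    def test_pure_noise_rarely_triggers(self):
        rng = np.random.default_rng(42)
        spurious = 0
        for _ in range(1000):
            vals = 0.5 + rng.normal(0, 0.02, 160)
            spurious += onset_time(_trace(vals), k=3) is not None
        assert spurious < 100  # < 10% false positives

    def test_k1_is_more_permissive_than_k3(self):
        rng = np.random.default_rng(1)
        vals = 0.5 + rng.normal(0, 0.02, 160)
        vals[100] = 0.9  # a single-bin excursion
        assert onset_time(_trace(vals), k=1) is not None
        assert onset_time(_trace(vals), k=3) is None


class TestOnsetEquivariance:
    def test_shifting_modulation_shifts_detected_onset(self):
        """A modulation onset moved by delta moves the detected onset by
        delta, to within one trace-step (median over 3 sessions)."""
        from pptn_tonic.roc import normalized_activity_trace
        delta, step = 0.2, 0.02
        shifts = []
        for seed in (61, 62, 63):
            onsets = {}
            for lead in (0.15, 0.15 + delta):
                p = NeuronProfile("tonic_excitatory", 20.0,
                                  modulation_depth=40.0, onset_lead_s=lead)
                ts = simulate_neuron(p, n_blocks=48, seed=seed)
                tr = normalized_activity_trace(ts, filter_trials(ts.trials),
                                               span=(-0.8, 0.8), step=step)
                onsets[lead] = onset_time(tr, k=10).time_s
            shifts.append(onsets[0.15 + delta] - onsets[0.15])
        assert float(np.median(shifts)) == pytest.approx(delta, abs=step + 1e-9)


class TestRegression:
    def test_reward_driven_neuron_dissociates_predictors(self):
        p = NeuronProfile("unmodulated", 15.0, reward_mod_sign=1,
                          reward_mod_depth=8.0)
        ts = simulate_neuron(p, n_blocks=6, seed=20)
        res = regress_reward_vs_shape(ts, filter_trials(ts.trials))
        assert res.p_reward < 0.05
        assert res.coef_reward > 0

    def test_shape_driven_neuron_mirrors(self):
        # rate depends only on the FT shape: inject shape-locked cue spikes;
        # shape must come out significant every time, reward (a true null)
        # at most rarely
        shape_sig, reward_sig = 0, 0
        for seed in range(10):
            trials_df = trials_to_frame(generate_trial_sequence(
                TaskConfig(n_blocks=6, p_error=0.0), seed))
            rng = np.random.default_rng(100 + seed)
            spikes = {}
            for tr in frame_to_trials(trials_df):
                rate = 25.0 if tr.ft_shape == "square" else 5.0
                spikes[tr.trial_id] = np.sort(np.concatenate([
                    poisson_train(rng, 10.0, 0.0, tr.ft_onset_s),
                    poisson_train(rng, rate, tr.ft_onset_s, tr.end_s)]))
            ts = SpikeTrainSet("n0", spikes, trials_df)
            res = regress_reward_vs_shape(ts, filter_trials(trials_df))
            shape_sig += res.p_shape < 0.05
            reward_sig += res.p_reward < 0.05
        assert shape_sig == 10
        assert reward_sig <= 3

    def test_single_block_design_is_collinear(self):
        p = NeuronProfile("unmodulated", 15.0)
        ts = simulate_neuron(p, n_blocks=1, seed=22)
        assert regress_reward_vs_shape(ts, filter_trials(ts.trials)) is None


def test_profile_neuron_end_to_end():
    p = NeuronProfile("tonic_excitatory", 12.0, modulation_depth=12.0,
                      reward_mod_sign=1, reward_mod_depth=6.0,
                      onset_lead_s=0.1)
    ts = simulate_neuron(p, n_blocks=6, seed=30)
    prof = profile_neuron(ts)
    assert prof.tonic_category == "tonic_excitatory"
    assert prof.fixation_response_roc > 0.5
    assert prof.reward_mod_cue_roc > 0.5
    assert prof.onset_time_s is not None and prof.onset_sign == 1
    assert prof.regression is not None
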