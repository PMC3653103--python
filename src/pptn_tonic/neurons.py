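"""Synthetic neurons: rate profiles, spike trains, waveforms, populations.

The response taxonomy has three tonic categories.  Tonic excitatory neurons
step their rate up from a per-trial onset until reward delivery; tonic
suppressive neurons are the mirrored (subtracted) profile; unmodulated
neurons stay at baseline.  A signed reward-magnitude modulation can ride on
top of the tonic step between the reward cue (FT) and reward delivery, and
the onset can be locked either to the initial-stimulus onset or to the
anticipatory centering gaze shift (behavior-coupled neurons).  Error trials
carry no tonic modulation: the rate stays at baseline throughout.

Spike trains are sampled from the rate profile as an inhomogeneous Poisson
process by thinning; waveforms are a biphasic (negative-then-positive)
template so that the spike-duration measurement is exercised end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .spike_metrics import SpikeTrainSet
from .task import TaskConfig, TrialRecord, generate_trial_sequence, trials_to_frame

log = logging.getLogger(__name__)

CATEGORIES = ("tonic_excitatory", "tonic_suppressive", "unmodulated")
_CAT_SIGN = {"tonic_excitatory": 1.0, "tonic_suppressive": -1.0,
             "unmodulated": 0.0}


@dataclass(frozen=True)
class PhasicComponent:
    """A transient Gaussian rate bump locked to a task event."""

    event: str  # alignment event name ("stim", "ft", "st", "reward", "gaze")
    amplitude: float  # spikes/s
    latency_s: float
    width_s: float


@dataclass(frozen=True)
class NeuronProfile:
    """Ground-truth generative parameters of one synthetic neuron."""

    category: str
    baseline_rate: float
    modulation_depth: float = 0.0  # magnitude of the tonic step, spikes/s
    reward_mod_sign: int = 0  # rate-space sign of the large-reward effect
    reward_mod_depth: float = 0.0
    behavior_coupled: bool = False  # onset locked to gaze shift vs stimulus
    onset_lead_s: float = 0.0
    phasic_components: tuple[PhasicComponent, ...] = ()
    waveform_peak_separation_ms: float = 0.53

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be strictly positive")
        if self.category == "unmodulated" and self.modulation_depth != 0:
            raise ValueError("unmodulated neurons must have zero depth")
        if self.modulation_depth < 0 or self.reward_mod_depth < 0:
            raise ValueError("depths are magnitudes; use signs for direction")

    @property
    def rate_ceiling(self) -> float:
        """Upper bound on the rate profile (used by the thinning sampler)."""
        return (self.baseline_rate + self.modulation_depth
                + self.reward_mod_depth
                + sum(abs(pc.amplitude) for pc in self.phasic_components))


def _event_time(trial: TrialRecord, event: str) -> Optional[float]:
    return {
        "stim": trial.initial_stimulus_onset_s,
        "fp": trial.fp_onset_s,
        "ft": trial.ft_onset_s,
        "st": trial.st_onset_s,
        "reward": trial.reward_time_s,
        "gaze": trial.gaze_shift_time_s,
        "free_reward": trial.free_reward_time_s,
    }[event]


def tonic_onset_time(profile: NeuronProfile, trial: TrialRecord) -> float:
    """Per-trial time at which the tonic step begins."""
    anchor = (trial.gaze_shift_time_s if profile.behavior_coupled
              else trial.initial_stimulus_onset_s)
    return anchor + profile.onset_lead_s


def rate_profile(profile: NeuronProfile, trial: TrialRecord,
                 t: np.ndarray | float) -> np.ndarray:
    """Instantaneous firing rate (spikes/s) at times ``t`` within the trial.

    Success trials: the tonic step (signed by category) runs from the
    per-trial onset until reward delivery; the reward modulation
    (``reward_mod_sign * reward_mod_depth``, sign flipped on small-reward
    trials) runs from FT onset until reward delivery.  Error trials carry no
    modulation.  Negative rates are clipped to zero (logged at debug level).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    rate = np.full(t.shape, profile.baseline_rate)
    if trial.outcome == "success" and trial.reward_time_s is not None:
        end = trial.reward_time_s
        cat = _CAT_SIGN[profile.category]
        if cat != 0.0 and profile.modulation_depth > 0:
            onset = tonic_onset_time(profile, trial)
            rate += (cat * profile.modulation_depth
                     * ((t >= onset) & (t < end)))
        if profile.reward_mod_sign and profile.reward_mod_depth > 0:
            rsign = 1.0 if trial.reward_size == "large" else -1.0
            rate += (profile.reward_mod_sign * profile.reward_mod_depth
                     * rsign * ((t >= trial.ft_onset_s) & (t < end)))
    for pc in profile.phasic_components:
        t0 = _event_time(trial, pc.event)
        if t0 is None:
            continue
        z = (t - (t0 + pc.latency_s)) / pc.width_s
        rate += pc.amplitude * np.exp(-0.5 * z * z)
    if (rate < 0).any():
        log.debug("rate profile clipped at 0 for trial %d", trial.trial_id)
        rate = np.clip(rate, 0.0, None)
    return rate


def generate_spike_train(profile: NeuronProfile, trial: TrialRecord,
                         seed, t_stop: Optional[float] = None) -> np.ndarray:
    """Sample one trial's spike train by Poisson thinning.

    Homogeneous candidates at the profile's rate ceiling over
    ``[0, t_stop]`` are kept with probability ``rate(t) / ceiling``, giving
    an inhomogeneous Poisson process with intensity ``rate_profile``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_stop = trial.end_s if t_stop is None else t_stop
    ceiling = profile.rate_ceiling
    if ceiling <= 0 or t_stop <= 0:
        return np.empty(0)
    n = rng.poisson(ceiling * t_stop)
    if n == 0:
        return np.empty(0)
    times = np.sort(rng.uniform(0.0, t_stop, n))
    accept = rng.uniform(0.0, ceiling, n) < rate_profile(profile, trial, times)
    return times[accept]


def generate_waveform(profile: NeuronProfile, sampling_rate: float = 40_000.0,
                      seed=None, noise_sd: float = 0.0) -> np.ndarray:
    """Sampled biphasic action-potential template (arbitrary amplitude units).

    A negative Gaussian trough is followed, ``waveform_peak_separation_ms``
    later, by a positive Gaussian peak; optional additive white noise.
    """
    if sampling_rate < 20_000.0:
        raise ValueError("sampling_rate must be at least 20 kHz")
    sep_ms = profile.waveform_peak_separation_ms
    trough_ms = 0.8
    total_ms = trough_ms + sep_ms + 1.2
    t_ms = np.arange(int(round(total_ms * sampling_rate / 1000.0))) \
        / sampling_rate * 1000.0
    z1 = (t_ms - trough_ms) / 0.08
    z2 = (t_ms - (trough_ms + sep_ms)) / 0.12
    w = -1.0 * np.exp(-0.5 * z1 * z1) + 0.6 * np.exp(-0.5 * z2 * z2)
    if noise_sd > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        w = w + rng.normal(0.0, noise_sd, w.shape)
    return w


@dataclass
class NeuronRecording(SpikeTrainSet):
    """A synthetic session: spike trains per trial, plus the mean waveform."""

    waveform: Optional[np.ndarray] = None
    sampling_rate: float = 40_000.0


#: category proportions reported for the recorded population
DEFAULT_PROPORTIONS = (0.54, 0.16, 0.30)
#: median pre-fixation rates (spikes/s) per category
DEFAULT_BASELINE_MEDIANS = (9.6, 16.2, 12.0)
#: fraction of excitatory / suppressive neurons with reward-coupled rates
DEFAULT_P_REWARD_MOD = (0.20, 0.13, 0.0)
#: fraction with gaze-shift-locked (behavior-coupled) onsets
DEFAULT_P_BEHAVIOR = (0.20, 0.14, 0.0)


def split_by_proportions(n_total: int,
                         proportions: Sequence[float] = DEFAULT_PROPORTIONS,
                         ) -> tuple[int, int, int]:
    """Largest-remainder split of ``n_total`` into the three categories."""
    raw = np.asarray(proportions, dtype=float) * n_total
    base = np.floor(raw).astype(int)
    rem = n_total - base.sum()
    order = np.argsort(-(raw - base))
    for i in range(rem):
        base[order[i]] += 1
    return tuple(int(x) for x in base)


def sample_profile(category: str, rng: np.random.Generator, *,
                   reward_coupling: str = "matched",
                   p_reward_mod: Sequence[float] = DEFAULT_P_REWARD_MOD,
                   p_behavior: Sequence[float] = DEFAULT_P_BEHAVIOR,
                   depth_scale: float = 1.0,
                   reward_mod_scale: float = 0.5,
                   baseline_medians: Sequence[float] = DEFAULT_BASELINE_MEDIANS,
                   baseline_log_sd: float = 0.4,
                   waveform_sep_median_ms: float = 0.53,
                   ) -> NeuronProfile:
    """Draw one neuron's generative parameters for a given category.

    ``reward_coupling`` controls the dependence between the tonic direction
    and the reward-modulation sign: ``"matched"`` gives excitatory neurons
    positive and suppressive neurons negative reward modulation (the
    structure under study); ``"independent"`` draws the sign by fair coin
    (a null population for calibration); ``"none"`` disables reward
    modulation entirely.
    """
    ci = CATEGORIES.index(category)
    baseline = float(np.exp(np.log(baseline_medians[ci])
                            + rng.normal(0.0, baseline_log_sd)))
    depth = depth_scale * baseline if category != "unmodulated" else 0.0
    sign, rdepth = 0, 0.0
    if reward_coupling != "none" and rng.random() < p_reward_mod[ci]:
        if reward_coupling == "matched":
            sign = {0: 1, 1: -1, 2: 0}[ci]
        elif reward_coupling == "independent":
            sign = 1 if rng.random() < 0.5 else -1
        else:
            raise ValueError(f"unknown reward_coupling {reward_coupling!r}")
        if sign:
            rdepth = reward_mod_scale * baseline
    coupled = bool(rng.random() < p_behavior[ci]) if category != "unmodulated" else False
    if category == "unmodulated":
        lead = 0.0
    elif coupled:
        lead = float(rng.uniform(0.0, 0.1))  # shortly after the gaze shift
    else:
        lead = float(rng.uniform(-0.4, 0.2))  # re initial stimulus
    sep = float(np.exp(np.log(waveform_sep_median_ms) + rng.normal(0.0, 0.15)))
    return NeuronProfile(
        category=category, baseline_rate=baseline, modulation_depth=depth,
        reward_mod_sign=sign, reward_mod_depth=rdepth,
        behavior_coupled=coupled, onset_lead_s=lead,
        waveform_peak_separation_ms=sep)


def generate_population(n_per_category: Sequence[int], config: TaskConfig,
                        seed, *, reward_coupling: str = "matched",
                        waveform_noise_sd: float = 0.02,
                        **profile_kwargs,
                        ) -> list[tuple[NeuronRecording, NeuronProfile]]:
    """Simulate a population with known ground truth.

    ``n_per_category`` gives counts for (tonic_excitatory, tonic_suppressive,
    unmodulated).  Each neuron gets its own session (trial sequence) drawn
    from ``config``, per-trial spike trains, and a noisy waveform; the
    ground-truth :class:`NeuronProfile` is returned alongside each recording.
    """
    root = np.random.SeedSequence(seed)
    out: list[tuple[NeuronRecording, NeuronProfile]] = []
    idx = 0
    for category, n in zip(CATEGORIES, n_per_category):
        for _ in range(int(n)):
            ss_prof, ss_task, ss_spk, ss_wav = root.spawn(1)[0].spawn(4)
            rng = np.random.default_rng(ss_prof)
            profile = sample_profile(category, rng,
                                     reward_coupling=reward_coupling,
                                     **profile_kwargs)
            trials = generate_trial_sequence(config, ss_task)
            spk_rng = np.random.default_rng(ss_spk)
            spikes = {tr.trial_id: generate_spike_train(profile, tr, spk_rng)
                      for tr in trials}
            waveform = generate_waveform(profile, seed=ss_wav,
                                         noise_sd=waveform_noise_sd)
            rec = NeuronRecording(
                neuron_id=f"n{idx:04d}", spikes=spikes,
                trials=trials_to_frame(trials), waveform=waveform)
            out.append((rec, profile))
            idx += 1
    return out
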