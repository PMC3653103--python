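# Methods

This package re-implements, as a tested pipeline over synthetic data, the
spike-train analysis used to characterize tonic reward-prediction activity
in pedunculopontine tegmental nucleus (PPTN) neurons recorded during a
reward-biased visually guided saccade task. It has two halves: a
synthetic-data generator that emulates the task and the response taxonomy,
and the measurement chain (ROC normalization, tonic classification,
modulation indices, onset detection, population statistics) that is the
actual subject of the tests.

## The task model

A session is a sequence of `n_blocks` blocks; within a block the mapping
between the fixation-target (FT) shape and the reward magnitude is fixed
and it reverses at every block boundary, with block lengths drawn uniformly
from 20–30 trials. A trial runs: intertrial interval (fixed 1.5 s, or
jittered 1.5–2 s) → initial stimulus (an uninformative fixation point FP,
or directly the FT, depending on the task variant) → FT after 400–800 ms of
fixation → saccade target (ST) after 400–1500 ms → reward 100 or 300 ms
after the ST disappears. Large and small rewards are 3 vs 1 drops of juice.
Errors (default 10% of trials, split between fixation breaks and saccade
errors) truncate the trial at the failed event. Free rewards occur in the
intertrial interval with probability 0.05.

The reaction time to fixate the initial target (RTit) is the gaze-shift
time minus the stimulus onset; it is drawn from a Gaussian (mean −0.1 s,
SD 0.25 s, truncated to [−1.5, +3] s), so most gaze shifts are anticipatory
— the subject centers its gaze before the stimulus appears. No RTit
distribution is reported for the original task, so these values are a
choice: a mode slightly before stimulus onset with a long positive tail is
what the described "frequent anticipatory gaze shifts" imply qualitatively.
All times are seconds from trial start (the start of the preceding
intertrial interval), so the 600 ms pre-stimulus baseline window always
lies inside the trial's own span.

## The neuron model

Each synthetic neuron has a category — tonic excitatory, tonic suppressive,
or unmodulated — a baseline rate, and a tonic step of `modulation_depth`
spikes/s that runs from a per-trial onset until reward delivery (sign set
by the category; suppressive neurons are the exact mirror of excitatory
ones, clipped at 0 spikes/s). The onset is locked either to the
initial-stimulus onset or, for behavior-coupled neurons, to the anticipatory
centering gaze shift, plus a fixed lead. A signed reward modulation
(`reward_mod_sign × reward_mod_depth`, flipped on small-reward trials) rides
on top between FT onset and reward delivery — so the reward-cue period is
informative and the post-reward (outcome) period is not, matching the
observation that the differential response ends around reward delivery.
Error trials carry no modulation at all, and free rewards evoke no
response. Optional phasic components (Gaussian rate bumps locked to task
events) exist for realism but are off by default.

Population defaults: 54% excitatory / 16% suppressive / 30% unmodulated;
log-normal baseline rates with medians 9.6, 16.2 and 12 spikes/s
respectively (log-SD 0.4); tonic depth equal to the baseline; 20% of
excitatory neurons carry positive and 13% of suppressive neurons negative
reward modulation at half the baseline (the "matched" coupling — the
structure under study); 20% / 14% are behavior-coupled. An "independent"
coupling mode draws the reward-modulation sign by fair coin regardless of
category, giving a null population for calibration. Spike trains are
inhomogeneous Poisson, sampled by thinning against the profile's exact rate
ceiling. Waveforms are a biphasic template (negative trough, then a
positive peak `waveform_peak_separation_ms` later, median 0.53 ms) with
additive white noise.

What the generator deliberately does *not* emulate: rate drifts and
nonstationarity across a session, non-Poisson spiking statistics (real PPTN
irregularity indices are ~0.5–0.6, below the Poisson value), correlated
trial-to-trial excitability, eye-movement kinematics, and recording
artifacts. Passing tests therefore show that the measurement chain recovers
the generative structure it assumes, not that it is robust to everything
real recordings do.

## The measurement chain

**Tie-excluding ROC.** The core statistic is the probability that a
randomly chosen per-trial firing rate from the first condition exceeds one
from the second, with tied pairs excluded from numerator and denominator:
`roc = #{a > b} / #{a ≠ b}`. 1 means the first condition is always higher,
0 always lower, 0.5 no discrimination. When every pair ties the value is
0.5 (logged): with no informative pairs, non-discrimination is the only
consistent report. Note this differs from the conventional AUC, which gives
ties half credit.

**Normalized activity trace.** Per neuron, per alignment event: the ROC of
per-trial rates in a 200 ms window sliding in 10 ms steps against the
per-trial rates in the 600 ms pre-stimulus baseline window. Bins inside the
baseline span share spikes with the baseline sample, which biases them
slightly; bins are nevertheless computed everywhere (the overlap is a known
property of the display, and excluding them would leave holes in the
trace). Window convention is half-open `[a, b)` everywhere.

**Tonic classification.** Per-trial rates 0–600 ms after vs 600–0 ms before
the initial stimulus, two-sided Wilcoxon rank-sum at p < 0.05, direction by
the median difference. The rank-sum (unpaired) form is used even though the
two windows come from the same trials, following the source analysis. The
test uses the tie-corrected asymptotic normal approximation without
continuity correction; at the trial counts involved (≥50 per side) the
uncorrected form is closer to nominal (measured type-I error 4.8% at
α = 0.05), while the corrected form is conservative.

**Modulation indices.** Reward modulation: large- vs small-reward trials in
the cue (0–600 ms post-FT) and outcome (0–600 ms post-reward) windows,
large first, so ROC > 0.5 is positive reward modulation. Behavioral
modulation: short- vs long-RTit trials (per-neuron median split; ties at
the median go to the long side) in the pre-stimulus window. All analyses
use correct trials only, excluding the first three trials of each block
(adaptation to the contingency switch).

**Onset detection.** On the stimulus-aligned trace: mean and SD over the
baseline span, onset at the first run of at least K bins outside
mean ± 2 SD, scanning forward from the start of the span; the run must keep
a consistent direction (otherwise a noise dip chains into a genuine rise
and backdates the onset), and its sign is reported. Two numerical choices
matter here. First, when the trace step is much finer than the window,
neighbouring bins share most of their spikes, so the naive SD across
baseline bins badly underestimates the marginal bin noise; the SD is
instead estimated from differences between bins one full window apart,
which share no data. Second, K defaults to 3 (one bin reproduces the
literal single-crossing rule and is selectable), but because bins within a
window length are correlated, a persistence of K = window/step bins is the
setting that actually suppresses noise runs, and it is what the onset
characterization tests use. Even so, onsets are only identifiable to
roughly the window's rise time divided by the signal-to-noise ratio; at
feasible trial counts (~10³) this is a few tens of milliseconds, which is
why the equivariance tests run at a 20 ms step and characterize the
detector by its median behavior over independent sessions.

**Regression.** Per-trial cue-window rate regressed (OLS) on a large-reward
indicator and an FT-shape indicator. The block-wise contingency reversal
decorrelates the two predictors; with a single block they are collinear and
the result is withheld with an explanation. Indicator (0/1) coding is used
for both predictors — with only two reward levels, coding drops as 1/3
changes only the coefficient scale, not the inference. Classical
standard errors are used; heteroscedasticity-robust (HC3) inference was
evaluated and changed nothing measurable (the shape-null p-value is
calibrated: P(p > 0.1) = 0.89 ± 0.01 by simulation).

**Population statistics.** Spearman rank correlations between indices with
a two-sided permutation test: y is shuffled against x 20,000 times and
p = (1 + #{|ρ_perm| ≥ |ρ_obs|}) / (n_shuffles + 1), which keeps p off zero
and honours the floor 1/(n_shuffles+1). Absolute modulation strength is
|ROC − 0.5|. Frequency contrasts (e.g. pre-stimulus onsets in excitatory vs
suppressive neurons) use the Pearson chi-square without continuity
correction. Group firing-rate contrasts run all six pairwise rank-sum tests
among {excitatory, suppressive} × {pre, post} at the Bonferroni level
0.05/6. Heatmap rows sort by onset within category (absent onsets last,
ties by neuron id); population averages are unweighted pointwise means of
per-neuron traces on a common grid. Correlations include unmodulated
neurons — the scatter of indices over the whole population is the object
of interest, not only its significant corners.

## Reproducibility and problem sizes

Every stochastic step is a pure function of (configuration, seed); the
pipeline writes a manifest (config hash, seed, package versions) sufficient
to reproduce any output file. The test suite runs its heavier
characterizations at sizes chosen to make the checks decisive yet quick:
type-I calibration on 1,000 sessions of 60 trials (classification) and
1,000 replicates of n = 100 pairs at 2,000 shuffles (permutation test);
parameter recovery on 200 neurons at the default category mix with ~125
trials each; the regression dissociation rate over 300 simulated sessions;
onset equivariance over 5 sessions of ~1,200 trials. The analysis scripts
default to a 60-neuron population, which reproduces the qualitative
population structure; the index-correlation significances sharpen with
population size (hundreds of neurons), as the per-neuron indices are noisy.

## Known limitations

- The ROC trace is biased slightly below 0.5 even for a stationary neuron,
  because a 200 ms count is more dispersed and more discrete than a 600 ms
  baseline rate; the tie-excluding rule then favours the less dispersed
  sample. The bias is common to all bins and cancels in comparisons, but it
  means the baseline band center is not exactly 0.5.
- Onset detection inherits the 200 ms window's smear: a rate step at t
  begins to move the trace at t − 100 ms, and detected onsets sit between
  those two times depending on signal-to-noise. Onset *differences*
  (sorting, equivariance) are much better behaved than absolute onsets.
- The irregularity index of the generator's Poisson trains is ~0.85 (the
  5-interval CV of exponential gaps), higher than typically measured in
  this nucleus; the index is tested for its measurement properties
  (dimensionlessness, monotonicity in the gamma shape), not matched to a
  target value.
- With two reward levels and block-wise reversal, the reward and shape
  indicators are nearly but not exactly orthogonal in any finite session;
  the regression's power to dissociate them depends on having several
  blocks (≥4 recommended, 5 by default).
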