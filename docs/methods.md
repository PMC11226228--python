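# Methods

`riftpipe` simulates and analyzes rapid invisible frequency tagging (RIFT)
experiments on natural reading.  In such an experiment a target word in each
sentence sits on a patch whose luminance flickers sinusoidally at 60 Hz —
too fast to perceive — while MEG-like sensor data, a photodiode copy of the
flicker, and eye movements are recorded.  The phase-locked 60 Hz response in
visual sensors indexes how much covert attention the reader allocates to the
flickered word, in particular while the eyes still rest on the *pre-target*
word (parafoveal preview).  The package's question is methodological: given
the full analysis chain (epoching, filter-Hilbert coherence, permutation
sensor selection, condition contrasts, jackknife onset latencies), are
injected attention effects of realistic size recovered correctly, at the
right error rates?

## Generative model

One trial is: a fixation cross at sample 0 (the trial's phase reference), a
1.2 s pre-sentence baseline, then a sequence of first-pass fixations, one per
word, separated by 30 ms saccade gaps, with a 0.3 s tail.  Durations are
lognormal with mean 200 ms and SD 70 ms (parameterized by moment matching);
for incongruent trials the target word's first-fixation mean is increased by
`target_ffd_effect_ms` (default +30 ms), while the pre-target duration
distribution is identical across conditions.  A single optional second-pass
refixation (probability 0.1) models regressions.  Per-subject reading-speed
multipliers divide all durations.

The photodiode channel carries the clean tagging sinusoid for the whole
trial (the tracking disk flickers throughout), with phase 0 at the
cross-fixation onset.  Sensor channels contain unit-variance noise, an equal
mix of 1/f-shaped ("pink") and white noise — a deliberately reduced stand-in
for broadband MEG spectra.  The `n_tagged_channels` first channels
additionally carry the tagging sinusoid with instantaneous amplitude

    a(t) = snr * envelope(word offset fixated at t) * condition_factor(t),

where the attention envelope defaults to
{N−4: 0, N−3: 0.2, N−2: 0.45, N−1: 1.0, N: 0.75, N+1: 0.25, N+2: 0, N+3: 0}
— left-skewed with its peak on the pre-target word — and level changes ramp
linearly over 50 ms at each fixation onset.  The two congruency effects are
injected only within pre-target fixation intervals of incongruent trials:
the amplitude is multiplied by `amplitude_factor_incongruent` (default 0.8)
and the ramp onset is delayed by `latency_shift_ms` (default +25 ms).
Before sentence onset no tagging component exists in any sensor channel.

`snr` is the peak tagging amplitude over the noise SD.  The default 0.15
was fixed by calibration so that single-trial pre-target 60 Hz coherence
lands around 0.2–0.5 — the plausible range for a clearly detectable but not
saturated tagging response — with the permutation selection then finding the
tagged channels essentially always and the non-tagged ones at the nominal
false-alarm rate.

Defaults mirror a full study: 34 subjects, 80 trials per condition, 12-word
sentences with the target mid-sentence.  The sensor array is scaled from
306 MEG sensors (52 candidate visual sensors, ~8 selected) down to 24
channels with 6 tagged; all statistics here are per-channel, so array size
affects runtime only.

What the generator does *not* emulate: volume conduction and sensor
covariance, eye/muscle/cardiac artifacts, word-length and landing-position
variability, skipped words, saccade-duration variability, head movement, or
harmonic tagging responses.  Passing recovery tests therefore show that the
statistics behave correctly under the stated signal model, not that the
pipeline is robust to every property of real recordings.

## Analysis chain

**Epochs.**  Fixation-aligned epochs span [−0.5, +0.5] s around first-pass
fixation onsets; fixations shorter than 0.08 s or longer than 1 s are
discarded (closed interval: exactly 0.08 s and 1 s survive).  Baseline
epochs span [0, 1] s from the cross-fixation onset.  Sample convention:
endpoints inclusive, so a 1 s epoch at 1000 Hz has 1001 samples.

**Coherence.**  Epochs are band-pass filtered per centre frequency (40–80 Hz
in 2 Hz steps, centre ±5 Hz, zero-phase two-pass 4th-order Butterworth; the
60 Hz band is 55–65 Hz) and Hilbert-transformed.  The photodiode is
amplitude-normalized per epoch beforehand.  With analytic magnitudes m and
sensor–photodiode phase differences φ, the trialwise coherence over n
epochs at time t is

    coh(t) = |Σ_j m_xj(t) m_yj(t) e^{iφ_xyj(t)}|² / (Σ_j m_xj(t)² · Σ_j m_yj(t)²),

a magnitude-weighted phase-locking statistic bounded in [0, 1] by
Cauchy–Schwarz, equal to 1 for n = 1 or perfect locking, with expectation
≈ 1/n under independent phases.  Zero-denominator time points are NaN and
excluded from averages.  The outer 50 ms of each epoch are excluded from
time-averaged summaries as filter-edge territory (full ring-down of this
narrow filter takes ~0.3 s; time averages and phase statistics are far less
edge-sensitive than instantaneous magnitude).

The pipeline computes analytic signals once per subject on the *continuous*
recordings and slices epochs out of them, which is algebraically the same
statistic without per-epoch edge ringing and ~2.5× faster; the epoch-based
path remains the API for user-supplied epoch data, and a test pins the
agreement of the two routes on time-averaged coherence.

**Sensor selection.**  Per channel, the pre-target vs baseline coherence
difference is converted to
z = [(atanh|coh₁| − bias₁) − (atanh|coh₂| − bias₂)] / √(bias₁ + bias₂)
with biasᵢ = 1/(2nᵢ − 2), and referred to a Monte-Carlo null built by
shuffling epoch labels between the pooled conditions (default 5000
shuffles, shared across channels; right-sided p = 0.01, add-one p-value
estimator so p is never 0).  Subjects with no selected channel are dropped
from downstream contrasts.  NaN z-statistics (degenerate inputs) map to
p = 1.

**Condition contrasts.**  Trial counts are equalized by seeded random
subsampling of the larger condition.  Coherence at 60 Hz is averaged over a
subject's selected channels and over [0, d_min], where d_min is the
minimum pre-target first-fixation duration pooled over both conditions —
the window can therefore never include post-fixation (target-driven)
signal.  Group inference is a two-sided paired t-test with Cohen's d on the
paired differences; a zero-variance difference is flagged (±inf) rather than
silently tested.

**Onset latency.**  The latency of a coherence time course is the time of
the first sample at or above cohmin + (cohmax − cohmin)/2 within the search
window, at the 1 ms sample resolution (a step at 100 ms has latency exactly
100 ms; earliest sample wins ties).  The group condition difference
D = latency(incongruent) − latency(congruent) is computed from the
all-subject average curves; its standard error comes from the
leave-one-subject-out jackknife,
S_D = √(((n−1)/n) Σᵢ (D₋ᵢ − J̄)²), with t = D/S_D on n−1 degrees of freedom.

The default search window is (−0.15, 0.45) s around pre-target fixation
onset.  The lower bound sits on the shared pre-onset plateau deliberately:
with ±5 Hz smoothing the coherence rise is smeared over ~150 ms, so a window
starting at fixation onset cuts the rising flank mid-smear, makes the
in-window minimum (hence the half-max level) condition-dependent, and
compresses a true 25 ms onset shift to ~12–16 ms (verified on noise-free
curves).  Starting 150 ms earlier restores the recovered shift to within
~1 ms of the injected value; the upper bound keeps clear of the last 50 ms
of the epoch.

**Behavior.**  First-fixation durations take the earliest pass-1 fixation
per word and trial; total gaze sums all passes; refixation likelihood is the
proportion of trials with any pass > 1 fixation.  Reading speed is words per
second over congruent sentences, with per-sentence reading time defined as
the summed fixation durations of the trial (the generator does not model
display-side trigger timing, so fixation time is the deterministic
equivalent of on-screen time).  The brain–behavior link is the Spearman rank
correlation (midranks for ties) between the per-subject pre-target coherence
difference (incongruent − congruent) and reading speed.

## Numerical and design choices

- Flicker phase is 0 at cross-fixation onset; determinism over realism.
- Lognormal duration parameters are matched to the requested mean/SD;
  SD = 0 degenerates to constant durations.
- Permutation p-values use (1 + #{z_null ≥ z_obs})/(1 + n_perm).
- No multiple-comparison correction across channels; the candidate-channel
  subset plays the role of the anatomical sensor restriction.
- Target-word epochs do not exclude trials in which the pre-target word was
  skipped.
- Word skipping simply omits a trial from that word position's analysis.
- Equalization, selection and all other stochastic stages draw their seeds
  from one master seed via `SeedSequence` spawning; reports log every
  derived seed.

## Problem sizes in calibration and replicate runs

Replicate sweeps use reduced problem sizes chosen once: type-I-error
calibration runs single subjects with 15 trials per condition and 20
channels at snr 0 (the unit of replication is the channel decision);
parameter-recovery sweeps use 20 subjects, 40 trials per condition, 8
channels (3 tagged), snr 0.2 — a generous signal level so the half-max
latency estimator's crossing jitter stays well inside the injected 25 ms
shift — with 200 permutations for selection.  These sizes change estimator
precision, not the estimand; full-study defaults remain available on
`GroundTruth`.

## Known limitations

- The latency estimator is quantized to the sample grid (1 ms) and measures
  the half-max of a smoothed curve; with ±5 Hz smoothing, amplitude-scaling
  differences between conditions can still bleed a few ms into the latency
  contrast.
- The magnitude-weighted coherence estimator is biased upward by ≈ 1/n at
  low coherence; the bias term in the selection z-statistic corrects the
  Fisher-transformed difference, not the raw values.
- The permutation test assumes exchangeability of pre-target and baseline
  epochs under the null; structured artifacts that differ between reading
  and fixation-cross periods would violate it in real data.
- Baseline epochs start at the trial edge in the continuous-filtering fast
  path, so their first ~50 ms carry filter warm-up; time-averaged baseline
  coherence is chance-level either way.
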