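# Methods

This note documents the models, estimators and design decisions behind
`speechcoh`, in the order data flows through the package.

## Speech envelopes

The auditory envelope is the full-wave rectified waveform low-pass
filtered at 30 Hz. The filter is a 4th-order Butterworth applied
forward-backward (`sosfiltfilt`), so the envelope has zero group delay —
important because downstream coherence phase is meaningful. Zero-phase
filtering can ring slightly below zero; the envelope is therefore
"nonnegative up to ringing" (bounded near 1% of the peak) and deliberately
not clipped, which would distort its spectrum. Envelopes are brought to
the neural sampling rate (default 250 Hz) by polyphase resampling with a
Kaiser anti-alias window; upsampling is refused rather than silently
interpolated. An amplitude `scale` (e.g. 1e-10 to match neural units) is
supported for fidelity with acquisition pipelines but is cosmetic:
coherence is invariant to per-signal positive rescaling, a property the
tests check explicitly.

The visual envelope is a lip-aperture area trace consumed as two-column
delimited text (time, area). It is placed on a uniform grid at the video
frame rate with interior gaps filled linearly; nonmonotone time stamps and
negative areas are rejected. Extracting lip contours from video frames is
out of scope.

## Noise vocoder

The vocoder filters speech into `n_bands` logarithmically spaced bands
(default 16 between 70 and 5000 Hz; 6th-order zero-phase Butterworth
bandpass), extracts per-band envelopes by *half-wave* rectification and
30 Hz low-pass (the analysis envelope above uses full-wave rectification;
the two paths are intentionally separate code), and mixes each band
envelope with the broadband envelope in proportion `p`:

    env_final(b) = p · env(b) + (1 − p) · env(broadband)

Mixed envelopes modulate per-band white noise filtered with the same
bandpass filters (which keeps each noise carrier inside its band), the
bands are summed and the output RMS is matched to the input. `p` grades
acoustic clarity continuously: `p = 0` makes every band carry the
broadband envelope (1-channel vocoding, unintelligible), `p = 1` is
ordinary 16-channel vocoding (intelligible); 0.2 and 0.7 are typical
low/high clarity settings. Two reference vocoders
(`vocode_reference_1channel`, `vocode_reference_nchannel`) implement the
limit cases through independent code paths sharing the seeded noise; the
acceptance suite requires bit-identical agreement at `p = 0` and `p = 1`.
The broadband envelope is low-pass filtered identically to the band
envelopes before mixing.

## Spectral estimation

Epochs (0–5 s, matched between neural and envelope trials) are tapered
with a single Hanning window and Fourier transformed whole; auto- and
cross-spectra are averaged across trials before any ratio is formed.
Requested analysis frequencies are mapped to the nearest native FFT bin
(native resolution 0.2 Hz for 5 s epochs; a requested grid finer than the
native resolution is an error, not a silent aliasing). Multitaper and
wavelet estimators are out of scope.

Coherence is reported as the magnitude (not squared) ratio. Conventions:
bins with zero power yield coherence 0 rather than NaN; a single trial
yields coherence exactly 1 at all powered bins (the rank-1 artifact that
motivates multi-trial estimation, kept visible rather than masked). For
partial coherence, bins where the conditioning signal has zero power fall
back to ordinary coherence, and numerically nonpositive partial
auto-spectra clip the estimate to 0. With `y = z` the partial
cross-spectrum vanishes algebraically and the estimate is exactly 0.

The aperiodic profile of envelope spectra is summarised by a least-squares
line in (log f, log P); band-limited structure (the 2–8 Hz syllable bump)
appears as positive residuals.

## Permutation baselines

Chance-level coherence is estimated by re-pairing neural trials with
envelope trials under a uniform random derangement (rejection sampling;
no trial keeps its original partner) and averaging the resulting maps over
`n_perm = 100` re-pairings. For partial-coherence baselines both envelope
streams are permuted with the *same* derangement, preserving the stimulus
AV-coherence structure under the null — the alternative (independent
permutations) would test against a null in which the stimuli themselves
are decoupled, which is not the hypothesis. Re-pairing is performed within
the analysed trial set (i.e. within condition). The true-minus-permuted
difference is approximately normal, zero-centered under independence
(checked at ±2 SE over 50 simulated subjects) and unbounded below, making
it suitable for t-based group statistics.

The stimulus-level AV coherence test permutes the assignment of auditory
to visual envelopes (full permutations, 5000 by default), computes
one-tailed p-values with the add-one convention
`p = (#permuted ≥ observed + 1)/(n_perm + 1)` — so p is never smaller than
`1/(n_perm+1)` — and Bonferroni-corrects across frequencies.

Unequal trial counts between conditions are handled by subsampling the
abundant condition without replacement to the scarcer condition's count,
repeating 100 times and averaging the estimator output.

## Cluster statistics

Group-level inference uses per-cell one-sample t statistics over subjects'
true-minus-permuted maps, a cluster-defining threshold expressed as a
p-value converted to a t quantile with n−1 degrees of freedom (0.05
default; 0.005 available for stricter map summaries), connectivity =
channel adjacency within a frequency plus ±1 frequency bin within a
channel, cluster mass = summed t, and a max-cluster-mass null from random
per-subject sign flips (the exchangeability argument: under the null the
sign of each subject's true-minus-permuted difference is arbitrary). The
positive tail is the default since above-baseline coherence is the
directional hypothesis. `n_perm="all"` enumerates all 2^n sign flips; the
tests verify exact agreement with a brute-force enumeration and with the
MNE implementation of the same algorithm on the observed clustering.
Constant-zero cells have undefined t and are treated as sub-threshold with
a warning. ROI summaries average over a labelled channel set and the
2–6 Hz band before paired t contrasts (one-tailed against the baseline,
two-tailed between conditions; identical pairs return t = 0, p = 1, while
a constant nonzero difference is flagged as undefined).

## Behavior

Word report is scored as the percentage of target words present in the
response regardless of order, with multiset matching: each target token is
creditable once, and repeated target words require repeated responses.
Normalisation lowercases, strips punctuation and keeps contractions as
single tokens; no stemming, and morphological variants do not match
(exact-match policy, documented rather than configurable).

Hartigan's dip statistic (sup-distance between the empirical CDF and the
nearest unimodal CDF) is computed by the classical iterative
convex-minorant/concave-majorant algorithm, maintained in counts and with
the 1/(2n) lower bound enforced. It is validated against an independent
brute-force oracle that minimises the sup-distance over unimodal CDFs on a
grid by linear programming (convex-then-concave constraints, jump allowed
at the mode). p-values come from Monte-Carlo calibration against uniform
samples of the same size — the conventional least-favourable unimodal
null — with a cached, seeded null table (2000 replicates by default).

Correlations are Pearson r with the parametric t-transform p-value (one-
or two-tailed as requested) and a percentile bootstrap CI from 1000
subject resamples; degenerate resamples with zero variance are skipped.

## Synthetic ground truth

The generator emulates the structure of an audio-visual vocoded-sentence
experiment: five conditions (AO_high, AO_low, AV_high, AV_low, VO),
55 trials per condition, 5 s epochs at 250 Hz. Defaults chosen where the
emulated design does not pin them down: envelope spectra are 1/f
(`noise_exponent = 1`), the AV coupling band is 2–8 Hz, and the
asymptotic in-band AV envelope coherence is 0.5 — mid-range for natural
speech materials. Envelope pairs share a band-limited Fourier component
with weight `sqrt(av_env_coherence)` (giving magnitude coherence equal to
`av_env_coherence` in-band and chance outside), are normalised to unit
variance and shifted nonnegative.

Neural channels come in labelled groups ("STG", "occipital", "other"; 9
channels each by default, laid out on 2-D grids with 4-neighbour adjacency
and no between-group neighbours). Each channel is unit-variance 1/f noise
plus `gain × lagged standardised envelope` for every stream present in the
condition; default gains are 0.5 noise-SD for the preferred modality
(auditory in STG, visual in occipital) and 0 elsewhere. In VO the auditory
stream drives nothing directly, yet visually driven channels still
correlate with the absent auditory envelope through the built-in AV
coherence — exactly the confound partial coherence must resolve, and the
basis of the leakage-removal acceptance test. Cohorts add per-subject
lognormal gain jitter (sd 0.2 on the log scale) so group statistics have
realistic spread.

What the generator does *not* emulate: sensor physics and field spread,
head geometry and source mixing, artifacts (eye movements, cardiac),
autocorrelated across-trial structure, or realistic envelope
non-Gaussianity. Passing tests therefore demonstrate correctness of the
estimators and calibration of the statistics under the stated generative
model, not robustness to every property of real recordings.

## Problem sizes and numerical choices

The test and acceptance simulations use deliberately compact sizes chosen
to make the statistical checks well-powered yet quick: 14–50 simulated
subjects depending on the check, 15–60 trials, 100–5000 permutations
(500 sign flips per replicate in the familywise-error calibration, 200
replicates), and 2–8 Hz analysis grids at 1 Hz steps. Scaling any of these
up changes precision, not logic. All randomness flows through explicit
integer seeds (NumPy `default_rng`/`SeedSequence`); identical seeds give
bit-identical outputs, which the determinism tests assert across every
stage. The pipeline manifest records the configuration and SHA-256 hashes
of all written artifacts.

## Known limitations

- Coherence bias: with L trials, mean squared coherence of independent
  signals is ≈ 1/L; the permuted baseline exists precisely to absorb this
  bias, and no analytic bias correction is applied.
- The dip test's uniform-null calibration is conservative for peaked
  unimodal alternatives at small n.
- The cluster test controls familywise error at the cluster level; cluster
  extent has no localisation guarantee at the cell level.
- WAV I/O supports PCM mono files only.
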