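# speechcoh

Coherence analysis of neural phase-locking to audio-visual speech
envelopes.

When someone watches a talker, slow (syllable-rate) modulations arrive
through two channels at once: the acoustic amplitude envelope of the voice
and the opening-and-closing of the lips. Multichannel neural recordings
(MEG/EEG) phase-lock to both. Because the two envelopes are themselves
correlated, apparent "auditory" tracking in visual cortex (or vice versa)
can be inherited rather than genuine — the methodological knot this
package exists to untie. It is aimed at researchers analysing
envelope-tracking experiments and at anyone who wants a tested,
self-contained reference implementation of the statistical machinery.

## What it computes

**Coherence** between signals *i*, *j* at frequency *f*, from
Hanning-tapered per-epoch spectra averaged across trials:

    Coh_ij(f) = |CSD_ij(f)| / sqrt(Pow_i(f) · Pow_j(f))

**Partial coherence** conditions both signals on a third signal *z*
(Rosenberg-style conditioned spectra), removing the linear contribution of
the competing envelope:

    S_xy|z = S_xy − S_xz S_zy / S_zz,   S_xx|z = S_xx − |S_xz|² / S_zz
    PCoh_xy|z(f) = |S_xy|z| / sqrt(S_xx|z · S_yy|z)

**Permutation null baselines** re-pair neural trials with mismatched
stimulus envelopes (derangements, averaged over 100 re-pairings by
default); the true-minus-permuted difference is zero-centered under the
null and is the statistic carried into group analysis.

**Cluster-based permutation tests** (per-cell one-sample t, connected
channel×frequency clusters, max-cluster-mass null from per-subject sign
flips) control the familywise error over the sensor-frequency search
space.

Around this core: a graded-clarity noise vocoder
(`env_final(b) = p·env(b) + (1−p)·env(broadband)` over 16 log-spaced bands,
70–5000 Hz), envelope extraction/conditioning, lip-aperture trace
ingestion, word-report scoring, Hartigan's dip test, bootstrap
correlations, and a synthetic generator producing AV envelope pairs and
coupled multichannel recordings with known ground truth.

## Worked example

The package's central discriminative property — partial coherence
separating inherited from genuine cross-modal coupling — in a simulation
where channels are driven *only* by the visual envelope while the two
envelopes cohere at 0.6 in the 2–8 Hz band
(`python examples/04_partial_coherence_leakage.py`):

```
visual drive only:
  ordinary auditory effect +0.1672 (p=4.2e-10)
  partial  auditory effect +0.0034 (p=0.29)
visual + auditory drive:
  ordinary auditory effect +0.4671 (p=2.7e-15)
  partial  auditory effect +0.2504 (p=4.1e-12)
```

Ordinary coherence with the auditory envelope is strongly "significant"
even though no auditory drive exists — pure leakage through the AV
envelope correlation. Partialling out the visual envelope collapses it to
chance, and it returns only when genuine auditory coupling is added.

The other scripts in `examples/` are one capability each: envelope
extraction and vocoding, stimulus AV-coherence testing, baseline
construction, cluster statistics, and behavioral analysis. A thin CLI
(`speechcoh simulate | vocode | envelope | coherence | cluster-test |
behavior | report`) wraps the same functions for shell use.

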