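"""Extract a speech envelope and noise-vocode the waveform at two clarity levels.

Builds a modulated-noise stand-in for a spoken sentence, extracts its
amplitude envelope (full-wave rectification + 30 Hz low-pass), then vocodes
it with the graded-clarity mixer and shows that a higher mixing proportion
p preserves more of the per-band envelope structure.
"""

import numpy as np

from speechcoh import VocoderParams, band_envelopes, condition_envelope, \
    extract_auditory_envelope, vocode

fs = 16000
rng = np.random.default_rng(0)
t = np.arange(2 * fs) / fs
# 4 Hz syllable-rate modulation on broadband noise
waveform = (1 + 0.9 * np.sin(2 * np.pi * 4 * t)) * rng.standard_normal(t.size)

env = extract_auditory_envelope(waveform, fs)
env250 = condition_envelope(env, target_fs=250)
print(f"envelope: {len(env)} samples at {env.fs:g} Hz "
      f"-> conditioned to {len(env250)} samples at {env250.fs:g} Hz")

orig_rows, _ = band_envelopes(waveform, fs)
for p in (0.2, 0.7):
    out = vocode(waveform, fs, VocoderParams(p=p), seed=7)
    rows, _ = band_envelopes(out, fs)
    r = np.mean([np.corrcoef(orig_rows[b], rows[b])[0, 1] for b in range(16)])
    print(f"p={p}: mean per-band envelope correlation with original = {r:.3f}")

# Higher p keeps band-specific envelopes intact (clearer speech); at low p
# every band carries the broadband envelope, degrading spectral detail.
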