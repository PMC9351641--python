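"""Neural-envelope coherence against a permuted (derangement) baseline.

Simulates one subject's audio-visual condition, computes the coherence of
every channel with the auditory envelope, estimates the chance level by
re-pairing trials 50 times, and averages the true-minus-permuted effect
within the labelled channel groups.
"""

import numpy as np

from speechcoh import (SyntheticConfig, coherence_with_baseline,
                       generate_envelope_trials, generate_recording, roi_average)

cfg = SyntheticConfig(n_trials_per_condition=40)
aud, vis = generate_envelope_trials(cfg, seed=10)
rec = generate_recording(cfg, aud, vis, "AV_low", seed=11)

cmap = coherence_with_baseline(rec, aud, fs=cfg.fs,
                               freq_grid=np.arange(2.0, 9.0),
                               n_perm=50, seed=12)
print(f"coherence map: {cmap.values.shape[0]} channels x "
      f"{cmap.values.shape[1]} frequencies, {cmap.n_trials} trials")
for roi in ("STG", "occipital", "other"):
    eff = roi_average(cmap, rec.groups[roi], band=(2, 6))
    print(f"{roi:>10}: true-minus-permuted auditory coherence = {eff:+.4f}")

# Only the auditory-coupled STG group rises clearly above the permutation
# baseline; uncoupled channels sit near zero, as the null construction
# guarantees.
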