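"""Synthetic audio-visual speech and neural data with known ground truth.

The generator emulates the structure of an audio-visual sentence MEG
study: five conditions (audio-only at high/low clarity, audio-visual at
high/low clarity, visual-only) with 55 trials per condition, 0-5 s epochs
at 250 Hz.  Stimulus envelopes are 1/f-spectrum signals whose auditory and
visual streams share a band-limited component confined to the syllable
band (2-8 Hz by default), reproducing the above-chance audio-visual
envelope coherence of natural speech.  Neural channels are organised into
labelled groups ("STG", "occipital", "other"); each group mixes the
lagged auditory and visual envelopes with configurable gains into 1/f
background noise, so the ground-truth coupling that every estimator should
recover is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import EpochedRecording
from .envelopes import EnvelopeSignal

__all__ = [
    "GroupSpec",
    "SyntheticConfig",
    "DEFAULT_GROUPS",
    "generate_av_envelope_pair",
    "generate_envelope_trials",
    "generate_recording",
    "generate_subject",
    "generate_behavioral_cohort",
    "grid_adjacency",
    "jitter_config",
]

CONDITIONS = ("AO_high", "AO_low", "AV_high", "AV_low", "VO")

#: which envelope streams physically drive neural activity per condition
_DRIVERS = {
    "AO_high": ("auditory",),
    "AO_low": ("auditory",),
    "AV_high": ("auditory", "visual"),
    "AV_low": ("auditory", "visual"),
    "VO": ("visual",),
}


@dataclass(frozen=True)
class GroupSpec:
    """Coupling of one channel group to the speech envelopes.

    Gains are in units of noise standard deviations per unit-variance
    envelope; ``lag_ms`` delays the envelope before injection (coherence
    magnitude is lag-invariant, so lags exercise phase handling only).
    """

    n_channels: int
    gain_auditory: float = 0.0
    gain_visual: float = 0.0
    lag_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.gain_auditory < 0 or self.gain_visual < 0:
            raise ValueError("gains must be nonnegative")


DEFAULT_GROUPS: dict[str, GroupSpec] = {
    "STG": GroupSpec(n_channels=9, gain_auditory=0.5, gain_visual=0.0),
    "occipital": GroupSpec(n_channels=9, gain_auditory=0.0, gain_visual=0.5),
    "other": GroupSpec(n_channels=9),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth generator settings.

    av_env_coherence is the asymptotic coherence between the auditory and
    visual envelopes inside ``coupling_band``; outside the band the two
    streams are independent.  ``noise_exponent`` is the 1/f^beta slope of
    both envelope and neural background spectra.
    """

    n_trials_per_condition: int = 55
    epoch_s: float = 5.0
    fs: float = 250.0
    coupling_band: tuple[float, float] = (2.0, 8.0)
    av_env_coherence: float = 0.5
    channel_groups: dict[str, GroupSpec] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS))
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.av_env_coherence <= 1:
            raise ValueError("av_env_coherence must lie in [0, 1]")
        if self.av_env_coherence == 1.0:
            raise ValueError(
                "av_env_coherence = 1 with nonzero independent power is unrealisable")
        lo, hi = self.coupling_band
        if not 0 < lo < hi < self.fs / 2:
            raise ValueError("coupling_band must lie inside (0, fs/2)")
        if len(set(self.channel_groups)) != len(self.channel_groups):
            raise ValueError("group labels must be unique")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_s * self.fs))


def _one_over_f_amplitude(freqs: np.ndarray, beta: float) -> np.ndarray:
    amp = np.zeros_like(freqs)
    amp[freqs > 0] = freqs[freqs > 0] ** (-beta / 2.0)
    return amp


def _shaped_noise(rng: np.random.Generator, shape: tuple[int, ...], n: int,
                  fs: float, beta: float) -> np.ndarray:
    """1/f^beta noise via spectral shaping, unit variance per series.

    ``shape`` are the leading (series) dimensions; the time axis of length
    ``n`` is appended last.
    """
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    coeffs = (rng.standard_normal(shape + (freqs.size,))
              + 1j * rng.standard_normal(shape + (freqs.size,)))
    x = np.fft.irfft(coeffs * _one_over_f_amplitude(freqs, beta), n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def generate_av_envelope_pair(
    config: SyntheticConfig,
    trial_seed: int,
) -> tuple[EnvelopeSignal, EnvelopeSignal]:
    """One paired auditory/visual envelope trial.

    Both envelopes are 1/f-spectrum signals, nonnegative after an additive
    offset.  Inside ``coupling_band`` their Fourier coefficients share a
    common component with weight ``sqrt(av_env_coherence)``, so the
    many-trial coherence approaches ``av_env_coherence`` inside the band
    and chance outside it.
    """
    rng = np.random.default_rng(trial_seed)
    n, fs, beta = config.n_samples, config.fs, config.noise_exponent
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = _one_over_f_amplitude(freqs, beta)
    in_band = (freqs >= config.coupling_band[0]) & (freqs <= config.coupling_band[1])
    lam = config.av_env_coherence

    def coeffs() -> np.ndarray:
        return rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)

    shared = coeffs()
    out = []
    for modality in ("auditory", "visual"):
        own = coeffs()
        c = own.copy()
        c[in_band] = np.sqrt(lam) * shared[in_band] + np.sqrt(1 - lam) * own[in_band]
        x = np.fft.irfft(c * amp, n=n)
        x = x / np.std(x)
        x = x - x.min()  # positive offset -> nonnegative envelope
        out.append(EnvelopeSignal(x, fs=fs, modality=modality,
                                  label=f"trial{trial_seed}"))
    return out[0], out[1]


def generate_envelope_trials(
    config: SyntheticConfig,
    n_trials: int | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked (trials, samples) auditory and visual envelope arrays."""
    n_trials = config.n_trials_per_condition if n_trials is None else n_trials
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(entropy=seed)
    trial_seeds = ss.generate_state(n_trials)
    aud = np.empty((n_trials, config.n_samples))
    vis = np.empty((n_trials, config.n_samples))
    for i, ts in enumerate(trial_seeds):
        a, v = generate_av_envelope_pair(config, int(ts))
        aud[i], vis[i] = a.samples, v.samples
    return aud, vis


def _lag_samples(env: np.ndarray, lag_ms: float, fs: float) -> np.ndarray:
    shift = int(round(lag_ms * fs / 1000.0))
    return np.roll(env, shift, axis=-1)


def grid_adjacency(groups: dict[str, GroupSpec]) -> tuple[list[str], np.ndarray, dict[str, list[str]]]:
    """Channel names, adjacency and group membership for a synthetic layout.

    Each group's channels are laid out on a near-square 2-D grid with
    4-neighbour adjacency; groups are mutually non-adjacent blocks.
    """
    names: list[str] = []
    membership: dict[str, list[str]] = {}
    blocks = []
    for label, spec in groups.items():
        k = spec.n_channels
        ncol = int(np.ceil(np.sqrt(k)))
        adj = np.zeros((k, k), dtype=bool)
        for i in range(k):
            r, c = divmod(i, ncol)
            for j in range(k):
                r2, c2 = divmod(j, ncol)
                if abs(r - r2) + abs(c - c2) == 1:
                    adj[i, j] = True
        blocks.append(adj)
        chans = [f"{label}{i:02d}" for i in range(k)]
        names.extend(chans)
        membership[label] = chans
    n = len(names)
    full = np.zeros((n, n), dtype=bool)
    ofs = 0
    for adj in blocks:
        k = adj.shape[0]
        full[ofs:ofs + k, ofs:ofs + k] = adj
        ofs += k
    return names, full, membership


def generate_recording(
    config: SyntheticConfig,
    aud_trials: np.ndarray,
    vis_trials: np.ndarray,
    condition: str,
    seed: int | None = None,
) -> EpochedRecording:
    """Multichannel neural trials coupled to the given envelope trials.

    Each channel is 1/f noise plus ``gain * lagged standardised envelope``
    for every envelope stream that exists in ``condition``: auditory-only
    conditions carry no visual drive and the visual-only condition no
    auditory drive.  Channels in groups with zero gains are pure noise.
    Note that in VO, channels driven by the visual envelope still
    correlate with the (absent) auditory envelope through the built-in
    audio-visual envelope coherence — the situation partial coherence is
    designed to resolve.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    aud = np.asarray(aud_trials, dtype=float)
    vis = np.asarray(vis_trials, dtype=float)
    if aud.shape != vis.shape or aud.ndim != 2:
        raise ValueError("aud_trials and vis_trials must be matching (trials, samples)")
    if aud.shape[1] != config.n_samples:
        raise ValueError("envelope length must match config epoch")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(seed, CONDITIONS.index(condition))))
    drivers = _DRIVERS[condition]
    names, adjacency, membership = grid_adjacency(config.channel_groups)
    n_trials, n_samples = aud.shape
    n_channels = len(names)

    def standardise(e: np.ndarray) -> np.ndarray:
        mu = e.mean(axis=-1, keepdims=True)
        sd = e.std(axis=-1, keepdims=True)
        return (e - mu) / np.where(sd > 0, sd, 1.0)

    aud_s = standardise(aud)
    vis_s = standardise(vis)
    data = np.empty((n_trials, n_channels, n_samples))
    ch = 0
    for label, spec in config.channel_groups.items():
        a = _lag_samples(aud_s, spec.lag_ms, config.fs) if "auditory" in drivers else 0.0
        v = _lag_samples(vis_s, spec.lag_ms, config.fs) if "visual" in drivers else 0.0
        drive = spec.gain_auditory * a + spec.gain_visual * v
        noise = _shaped_noise(rng, (n_trials, spec.n_channels), n_samples,
                              config.fs, config.noise_exponent)
        if np.ndim(drive):
            drive = drive[:, None, :]
        data[:, ch:ch + spec.n_channels, :] = noise + drive
        ch += spec.n_channels
    return EpochedRecording(data, fs=config.fs, channel_names=names,
                            condition=condition, adjacency=adjacency,
                            groups=membership)


def generate_subject(
    config: SyntheticConfig,
    conditions: tuple[str, ...] = CONDITIONS,
    seed: int | None = None,
) -> dict[str, dict]:
    """Envelopes plus a coupled recording for each requested condition."""
    seed = config.seed if seed is None else seed
    out = {}
    for i, cond in enumerate(conditions):
        aud, vis = generate_envelope_trials(config, seed=seed * 7919 + i)
        rec = generate_recording(config, aud, vis, cond, seed=seed * 104729 + i)
        out[cond] = {"auditory": aud, "visual": vis, "recording": rec}
    return out


def jitter_config(config: SyntheticConfig, rng: np.random.Generator,
                  sd_log: float = 0.2) -> SyntheticConfig:
    """Per-subject lognormal jitter of the coupling gains.

    Gives group-level statistics a realistic between-subject spread while
    keeping the expected coupling structure intact.
    """
    groups = {
        label: replace(
            spec,
            gain_auditory=spec.gain_auditory * float(rng.lognormal(0.0, sd_log)),
            gain_visual=spec.gain_visual * float(rng.lognormal(0.0, sd_log)),
        )
        for label, spec in config.channel_groups.items()
    }
    return replace(config, channel_groups=groups)


def generate_behavioral_cohort(
    n_subjects: int,
    benefit_lipreading_r: float = 0.9,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject word-report accuracies across the five conditions.

    Lip-reading ability (VO accuracy) and the audio-visual benefit
    (AV_low minus AO_high) are drawn jointly so their population
    correlation equals ``benefit_lipreading_r``; condition means mimic a
    vocoded-sentence experiment (near-floor AO_low, intermediate matched
    AO_high/AV_low, high AV_high).  Accuracies are clipped to [0, 100].
    """
    if not -1 <= benefit_lipreading_r <= 1:
        raise ValueError("target correlation must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    r = benefit_lipreading_r
    z_vo = rng.standard_normal(n_subjects)
    z_ben = r * z_vo + np.sqrt(max(0.0, 1 - r**2)) * rng.standard_normal(n_subjects)
    vo = 8.0 + 4.0 * z_vo
    benefit = 12.0 * z_ben  # spread of AV_low - AO_high across listeners
    ao_high = 36.0 + 8.0 * rng.standard_normal(n_subjects)
    av_low = ao_high + benefit
    ao_low = 2.0 + 2.0 * rng.standard_normal(n_subjects)
    av_high = 78.0 + 8.0 * rng.standard_normal(n_subjects)
    df = pd.DataFrame({
        "subject": [f"S{i:02d}" for i in range(n_subjects)],
        "AO_high": ao_high, "AO_low": ao_low,
        "AV_high": av_high, "AV_low": av_low, "VO": vo,
    })
    for c in CONDITIONS:
        df[c] = df[c].clip(0.0, 100.0)
    df["av_benefit"] = df["AV_low"] - df["AO_high"]
    df["lip_reading"] = df["VO"]
    return df
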