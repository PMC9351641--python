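"""Graded-clarity noise vocoder.

Speech is filtered into logarithmically spaced bands between ``f_lo`` and
``f_hi``; each band's envelope (half-wave rectified, low-pass filtered
below 30 Hz) is mixed with the broadband envelope of the same signal in
proportion ``p``::

    env_final(b) = env(b) * p + env(broadband) * (1 - p)

and the mixed envelopes modulate band-limited white noise, which is then
recombined.  ``p`` grades acoustic clarity continuously: at ``p = 0`` every
band carries the broadband envelope (equivalent to 1-channel vocoding,
unintelligible); at ``p = 1`` the output is ordinary n-channel vocoded
speech (fully intelligible at 16 bands).  Intermediate values (0.2 and 0.7
are typical low/high clarity settings) interpolate between the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "VocoderParams",
    "log_band_edges",
    "band_envelopes",
    "mix_envelopes",
    "vocode",
    "vocode_reference_1channel",
    "vocode_reference_nchannel",
]


@dataclass(frozen=True)
class VocoderParams:
    """Vocoder configuration.

    n_bands : number of analysis bands (default 16)
    f_lo, f_hi : outer band edges in Hz (defaults 70 and 5000)
    p : clarity mixing proportion in [0, 1]
    env_cutoff : envelope low-pass corner in Hz (default 30)
    """

    n_bands: int = 16
    f_lo: float = 70.0
    f_hi: float = 5000.0
    p: float = 1.0
    env_cutoff: float = 30.0

    def __post_init__(self) -> None:
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("need 0 < f_lo < f_hi")
        if not 0 <= self.p <= 1:
            raise ValueError("p must lie in [0, 1]")


def log_band_edges(n_bands: int, f_lo: float, f_hi: float) -> np.ndarray:
    """Logarithmically spaced band edges: n_bands+1 values from f_lo to f_hi."""
    if n_bands < 1 or not 0 < f_lo < f_hi:
        raise ValueError("need n_bands >= 1 and 0 < f_lo < f_hi")
    return np.geomspace(f_lo, f_hi, n_bands + 1)


def _band_sos(lo: float, hi: float, fs: float, order: int = 6) -> np.ndarray:
    return signal.butter(order, [lo, hi], btype="band", fs=fs, output="sos")


def _halfwave_envelope(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    sos = signal.butter(4, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.maximum(x, 0.0))


def band_envelopes(
    waveform: np.ndarray,
    fs: float,
    params: VocoderParams = VocoderParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-band and broadband envelopes of a waveform.

    Returns ``(band_env, broadband_env)`` where ``band_env`` has one row per
    band (bandpass -> half-wave rectify -> low-pass) and ``broadband_env``
    is the same extraction applied to the unfiltered waveform.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1:
        raise ValueError("waveform must be 1-D")
    if not fs > 2 * params.f_hi:
        raise ValueError(f"fs={fs} must exceed twice f_hi={params.f_hi}")
    edges = log_band_edges(params.n_bands, params.f_lo, params.f_hi)
    rows = np.empty((params.n_bands, x.size))
    for b in range(params.n_bands):
        banded = signal.sosfiltfilt(_band_sos(edges[b], edges[b + 1], fs), x)
        rows[b] = _halfwave_envelope(banded, fs, params.env_cutoff)
    broadband = _halfwave_envelope(x, fs, params.env_cutoff)
    return rows, broadband


def mix_envelopes(band_env: np.ndarray, broadband_env: np.ndarray, p: float) -> np.ndarray:
    """env_final(b) = p * env(b) + (1 - p) * env(broadband), row-wise."""
    band_env = np.asarray(band_env, dtype=float)
    broadband_env = np.asarray(broadband_env, dtype=float)
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if band_env.ndim != 2 or broadband_env.shape != (band_env.shape[1],):
        raise ValueError("band_env must be (n_bands, n) and broadband_env (n,)")
    return p * band_env + (1.0 - p) * broadband_env[None, :]


def _band_noise(n: int, fs: float, edges: np.ndarray, seed: int) -> np.ndarray:
    """Per-band white noise, bandpass filtered into its own band."""
    rng = np.random.default_rng(seed)
    out = np.empty((edges.size - 1, n))
    for b in range(edges.size - 1):
        white = rng.standard_normal(n)
        out[b] = signal.sosfiltfilt(_band_sos(edges[b], edges[b + 1], fs), white)
    return out


def _recombine(noise: np.ndarray, envelopes: np.ndarray, reference: np.ndarray) -> np.ndarray:
    out = np.sum(noise * envelopes, axis=0)
    rms_out = np.sqrt(np.mean(out**2))
    rms_in = np.sqrt(np.mean(reference**2))
    if rms_out > 0:
        out = out * (rms_in / rms_out)
    return out


def vocode(
    waveform: np.ndarray,
    fs: float,
    params: VocoderParams = VocoderParams(),
    seed: int = 0,
) -> np.ndarray:
    """Noise-vocode a waveform at clarity ``params.p``.

    Deterministic given ``seed``; output RMS is matched to the input.
    """
    band_env, broadband = band_envelopes(waveform, fs, params)
    env_final = mix_envelopes(band_env, broadband, params.p)
    edges = log_band_edges(params.n_bands, params.f_lo, params.f_hi)
    noise = _band_noise(band_env.shape[1], fs, edges, seed)
    return _recombine(noise, env_final, np.asarray(waveform, dtype=float))


def vocode_reference_1channel(
    waveform: np.ndarray,
    fs: float,
    params: VocoderParams = VocoderParams(),
    seed: int = 0,
) -> np.ndarray:
    """Reference 1-channel vocoder sharing the mixing vocoder's noise bands.

    The broadband envelope modulates every noise band directly, bypassing
    per-band envelope extraction and mixing.  This is the independent code
    path against which the ``p = 0`` limit of :func:`vocode` is checked.
    """
    x = np.asarray(waveform, dtype=float)
    if not fs > 2 * params.f_hi:
        raise ValueError(f"fs={fs} must exceed twice f_hi={params.f_hi}")
    broadband = _halfwave_envelope(x, fs, params.env_cutoff)
    edges = log_band_edges(params.n_bands, params.f_lo, params.f_hi)
    noise = _band_noise(x.size, fs, edges, seed)
    envelopes = np.broadcast_to(broadband, (params.n_bands, x.size))
    return _recombine(noise, envelopes, x)


def vocode_reference_nchannel(
    waveform: np.ndarray,
    fs: float,
    params: VocoderParams = VocoderParams(),
    seed: int = 0,
) -> np.ndarray:
    """Reference n-channel vocoder: band envelopes modulate their own bands.

    No broadband mixing at all; the independent code path against which the
    ``p = 1`` limit of :func:`vocode` is checked.
    """
    band_env, _ = band_envelopes(waveform, fs, params)
    edges = log_band_edges(params.n_bands, params.f_lo, params.f_hi)
    noise = _band_noise(band_env.shape[1], fs, edges, seed)
    return _recombine(noise, band_env, np.asarray(waveform, dtype=float))
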