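"""Auditory and visual speech envelope extraction and conditioning.

The amplitude envelope of the acoustic speech waveform (full-wave
rectification followed by low-pass filtering at 30 Hz) and the lip-aperture
area trace are the two slow "speech envelope" signals against which neural
phase-locking is measured.  Both are brought to a common sampling rate
(typically 250 Hz, matching the downsampled neural recording) before any
spectral analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "EnvelopeSignal",
    "extract_auditory_envelope",
    "condition_envelope",
    "load_aperture_trace",
    "read_wav",
    "write_wav",
    "save_envelope",
    "load_envelope",
]

_MODALITIES = ("auditory", "visual")


@dataclass
class EnvelopeSignal:
    """A uniformly sampled, nonnegative-ish envelope time series.

    Parameters
    ----------
    samples : ndarray
        Envelope values, arbitrary amplitude units.  Auditory envelopes
        from :func:`extract_auditory_envelope` are nonnegative up to
        low-pass filter ringing (bounded by ~1% of the peak).
    fs : float
        Sampling rate in Hz.
    modality : {"auditory", "visual"}
    label : str
        Free-text identifier (e.g. sentence id).
    """

    samples: np.ndarray
    fs: float
    modality: str
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("envelope needs a 1-D sample array of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("envelope samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.modality not in _MODALITIES:
            raise ValueError(f"modality must be one of {_MODALITIES}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size


def _lowpass_sos(cutoff: float, fs: float, order: int = 4) -> np.ndarray:
    if not fs > 2 * cutoff:
        raise ValueError(f"fs={fs} must exceed twice the cutoff {cutoff}")
    return signal.butter(order, cutoff, btype="low", fs=fs, output="sos")


def extract_auditory_envelope(
    waveform: np.ndarray,
    fs: float,
    cutoff: float = 30.0,
    label: str = "",
) -> EnvelopeSignal:
    """Full-wave rectify and low-pass filter a speech waveform.

    The filter is a 4th-order Butterworth applied forward-backward
    (zero phase), so the envelope carries no group delay relative to the
    waveform.

    Parameters
    ----------
    waveform : array
        Mono audio samples.
    fs : float
        Audio sampling rate in Hz; must exceed ``2 * cutoff``.
    cutoff : float
        Low-pass corner frequency in Hz (default 30, the syllable-rate
        envelope band).
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1:
        raise ValueError("waveform must be mono (1-D)")
    if not np.all(np.isfinite(x)):
        raise ValueError("waveform contains non-finite samples")
    sos = _lowpass_sos(cutoff, fs)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.size <= padlen:
        raise ValueError(
            f"waveform length {x.size} too short for zero-phase filtering "
            f"(needs > {padlen} samples)"
        )
    env = signal.sosfiltfilt(sos, np.abs(x))
    return EnvelopeSignal(env, fs=fs, modality="auditory", label=label)


def condition_envelope(
    env: EnvelopeSignal,
    target_fs: float = 250.0,
    scale: float = 1.0,
) -> EnvelopeSignal:
    """Resample an envelope to the neural sampling rate and rescale it.

    Polyphase resampling (Kaiser-windowed anti-alias filter) preserves the
    duration to within one sample.  ``scale`` exists for fidelity with
    acquisition pipelines that match envelope amplitude to neural units
    (e.g. 1e-10); coherence is scale-invariant so the default is 1.
    Upsampling is not supported.
    """
    if target_fs > env.fs:
        raise ValueError(
            f"target_fs={target_fs} exceeds envelope fs={env.fs}; upsampling not supported"
        )
    if target_fs == env.fs:
        out = env.samples * scale
        return replace(env, samples=out)
    frac = Fraction(target_fs / env.fs).limit_denominator(10**6)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(env.samples, up, down, window=("kaiser", 5.0))
    return EnvelopeSignal(out * scale, fs=target_fs, modality=env.modality, label=env.label)


def load_aperture_trace(path: str | Path, fs_video: float) -> EnvelopeSignal:
    """Load a lip-aperture area trace from two-column delimited text.

    Columns are (time_s, area).  The trace is placed on a uniform grid at
    ``fs_video``; interior gaps (dropped frames) are filled by linear
    interpolation.  Time must be strictly increasing and areas nonnegative.
    """
    if not fs_video > 0:
        raise ValueError("fs_video must be positive")
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#",
                     skip_blank_lines=True)
    if df.shape[1] < 2:
        raise ValueError("aperture trace needs two columns: time_s, area")
    # tolerate a header row of column names
    try:
        float(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    t = df.iloc[:, 0].astype(float).to_numpy()
    a = df.iloc[:, 1].astype(float).to_numpy()
    if t.size < 2:
        raise ValueError("aperture trace needs at least two rows")
    if not np.all(np.diff(t) > 0):
        raise ValueError("aperture trace time column must be strictly increasing")
    if np.any(a < 0):
        raise ValueError("aperture areas must be nonnegative")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(a))):
        raise ValueError("aperture trace contains non-finite values")
    n = int(round((t[-1] - t[0]) * fs_video)) + 1
    grid = t[0] + np.arange(n) / fs_video
    area = np.interp(grid, t, a)
    return EnvelopeSignal(area, fs=fs_video, modality="visual",
                          label=str(Path(path).stem))


# -- I/O helpers --------------------------------------------------------------

def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a mono PCM WAV file as float samples in [-1, 1]."""
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("only mono WAV files are supported")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return data, float(fs)


def write_wav(path: str | Path, waveform: np.ndarray, fs: float) -> None:
    """Write float samples as 16-bit PCM, scaled to 90% full scale."""
    x = np.asarray(waveform, dtype=float)
    peak = np.max(np.abs(x)) or 1.0
    pcm = np.round(x / peak * 0.9 * 32767).astype(np.int16)
    wavfile.write(path, int(fs), pcm)


def save_envelope(env: EnvelopeSignal, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={env.fs}\n# modality={env.modality}\n# label={env.label}\n")
        np.savetxt(fh, env.samples)


def load_envelope(path: str | Path) -> EnvelopeSignal:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        samples = np.loadtxt(fh)
    return EnvelopeSignal(samples, fs=float(meta["fs"]), modality=meta["modality"],
                          label=meta.get("label", ""))
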