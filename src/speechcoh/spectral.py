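"""Cross-spectral estimation, coherence, partial coherence and 1/f fits.

Coherence between signals *i* and *j* at frequency *f* is the magnitude of
the trial-averaged cross-spectral density normalised by the geometric mean
of the trial-averaged power spectra::

    Coh_ij(f) = |CSD_ij(f)| / sqrt(Pow_i(f) * Pow_j(f))

Each 0-5 s epoch is tapered with a single Hanning window and Fourier
transformed whole; auto- and cross-spectra are averaged across trials
before the ratio is formed.  With a single trial the ratio is identically
1 (a rank-1 artifact), which is why all estimates here are multi-trial.

Partial coherence conditions the estimate on a third signal *z* (e.g. the
visual envelope when measuring neural-auditory coupling) by removing the
linear contribution of *z* from both spectra (Rosenberg-style conditioned
spectra)::

    S_xy|z = S_xy - S_xz S_zy / S_zz
    S_xx|z = S_xx - |S_xz|^2 / S_zz      (and symmetrically for y)
    PCoh   = |S_xy|z| / sqrt(S_xx|z * S_yy|z)

This is what separates genuine cross-modal neural coupling from coupling
inherited through the mutual coherence of the auditory and visual speech
envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

__all__ = [
    "SpectralEstimate",
    "CoherenceMap",
    "trial_csd",
    "coherence",
    "partial_coherence",
    "fit_one_over_f",
]


@dataclass
class SpectralEstimate:
    """Trial-averaged auto- and cross-spectra on a frequency grid.

    ``auto_x``/``cross_xy``/``cross_xz`` have shape (n_channels, n_freqs);
    ``auto_y``, ``auto_z`` and ``cross_zy`` have shape (n_freqs,).  ``z``
    spectra are present only when a conditioning signal was supplied.
    """

    freqs: np.ndarray
    auto_x: np.ndarray
    auto_y: np.ndarray
    cross_xy: np.ndarray
    n_trials: int
    channel_names: list[str]
    taper: str = "hanning"
    auto_z: np.ndarray | None = None
    cross_xz: np.ndarray | None = None
    cross_zy: np.ndarray | None = None

    @property
    def has_z(self) -> bool:
        return self.auto_z is not None


@dataclass
class CoherenceMap:
    """Coherence (or partial coherence) values per channel x frequency.

    ``baseline``, when present, is a same-shaped map of chance-level
    coherence from permuted trial pairings.
    """

    values: np.ndarray
    freqs: np.ndarray
    channel_names: list[str]
    kind: str = "coherence"
    n_trials: int = 0
    baseline: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("coherence values must lie in [0, 1]")
        if self.kind not in ("coherence", "partial_coherence"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.baseline is not None:
            self.baseline = np.atleast_2d(np.asarray(self.baseline, dtype=float))
            if self.baseline.shape != self.values.shape:
                raise ValueError("baseline shape must match values")

    @property
    def effect(self) -> np.ndarray:
        """True-minus-permuted coherence; zero-centered under the null."""
        if self.baseline is None:
            raise ValueError("no permuted baseline attached")
        return self.values - self.baseline

    def save(self, path: str | Path) -> None:
        """Delimited text values plus a JSON metadata sidecar."""
        path = Path(path)
        df = pd.DataFrame(self.values, index=self.channel_names,
                          columns=[f"{f:g}" for f in self.freqs])
        df.to_csv(path, sep="\t")
        meta = {"kind": self.kind, "n_trials": int(self.n_trials),
                "has_baseline": self.baseline is not None}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
        if self.baseline is not None:
            bdf = pd.DataFrame(self.baseline, index=self.channel_names,
                               columns=[f"{f:g}" for f in self.freqs])
            bdf.to_csv(path.with_suffix(path.suffix + ".baseline"), sep="\t")

    @classmethod
    def load(cls, path: str | Path) -> "CoherenceMap":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        baseline = None
        if meta.get("has_baseline"):
            baseline = pd.read_csv(path.with_suffix(path.suffix + ".baseline"),
                                   sep="\t", index_col=0).to_numpy()
        return cls(df.to_numpy(), freqs=df.columns.astype(float).to_numpy(),
                   channel_names=list(df.index), kind=meta["kind"],
                   n_trials=meta["n_trials"], baseline=baseline)


def _tapered_fft(trials: np.ndarray, taper: np.ndarray, bins: np.ndarray) -> np.ndarray:
    return np.fft.rfft(trials * taper, axis=-1)[..., bins]


def trial_csd(
    x_trials: np.ndarray,
    y_trials: np.ndarray,
    fs: float,
    freq_grid: np.ndarray,
    z_trials: np.ndarray | None = None,
    channel_names: list[str] | None = None,
) -> SpectralEstimate:
    """Hanning-tapered trial-averaged auto/cross spectra.

    ``x_trials`` may be (trials, samples) or (trials, channels, samples);
    ``y_trials`` (and optional ``z_trials``) are (trials, samples).
    Requested grid frequencies are mapped to the nearest native FFT bin;
    a grid finer than the native resolution is rejected.
    """
    x = np.asarray(x_trials, dtype=float)
    y = np.asarray(y_trials, dtype=float)
    if x.ndim == 2:
        x = x[:, None, :]
    if x.ndim != 3 or y.ndim != 2:
        raise ValueError("x_trials must be (trials[, channels], samples), y_trials (trials, samples)")
    if x.shape[0] != y.shape[0] or x.shape[-1] != y.shape[-1]:
        raise ValueError("x and y must agree in trial count and samples")
    n_trials, n_channels, n_samples = x.shape
    if n_trials < 1:
        raise ValueError("need at least one trial")

    grid = np.atleast_1d(np.asarray(freq_grid, dtype=float))
    if np.any(grid <= 0) or np.any(grid >= fs / 2):
        raise ValueError("freq_grid must lie strictly inside (0, fs/2)")
    df = fs / n_samples
    native = np.fft.rfftfreq(n_samples, 1.0 / fs)
    bins = np.round(grid / df).astype(int)
    if grid.size > 1 and np.min(np.diff(np.sort(grid))) < df * (1 - 1e-9):
        raise ValueError(
            f"frequency grid spacing finer than native resolution {df:g} Hz")
    if len(np.unique(bins)) != len(bins):
        raise ValueError("frequency grid maps multiple frequencies to one native bin")

    taper = np.hanning(n_samples)
    X = _tapered_fft(x, taper, bins)                    # (trials, channels, nf)
    Y = _tapered_fft(y, taper, bins)                    # (trials, nf)
    auto_x = np.mean(np.abs(X) ** 2, axis=0)
    auto_y = np.mean(np.abs(Y) ** 2, axis=0)
    cross_xy = np.mean(X * np.conj(Y)[:, None, :], axis=0)

    auto_z = cross_xz = cross_zy = None
    if z_trials is not None:
        z = np.asarray(z_trials, dtype=float)
        if z.shape != y.shape:
            raise ValueError("z_trials must match y_trials in shape")
        Z = _tapered_fft(z, taper, bins)
        auto_z = np.mean(np.abs(Z) ** 2, axis=0)
        cross_xz = np.mean(X * np.conj(Z)[:, None, :], axis=0)
        cross_zy = np.mean(Z * np.conj(Y), axis=0)

    if channel_names is None:
        channel_names = [f"ch{i:02d}" for i in range(n_channels)]
    return SpectralEstimate(
        freqs=native[bins], auto_x=auto_x, auto_y=auto_y, cross_xy=cross_xy,
        n_trials=n_trials, channel_names=list(channel_names),
        auto_z=auto_z, cross_xz=cross_xz, cross_zy=cross_zy,
    )


def _safe_ratio(num: np.ndarray, denom_sq: np.ndarray) -> np.ndarray:
    """|num| / sqrt(denom_sq) with 0/0 -> 0 and clipping to [0, 1]."""
    denom = np.sqrt(np.maximum(denom_sq, 0.0))
    out = np.zeros_like(num, dtype=float)
    np.divide(np.abs(num), denom, out=out, where=denom > 0)
    return np.clip(out, 0.0, 1.0)


def coherence(est: SpectralEstimate) -> CoherenceMap:
    """Magnitude coherence per channel x frequency (not squared)."""
    vals = _safe_ratio(est.cross_xy, est.auto_x * est.auto_y[None, :])
    return CoherenceMap(vals, freqs=est.freqs, channel_names=est.channel_names,
                        kind="coherence", n_trials=est.n_trials)


def partial_coherence(est: SpectralEstimate) -> CoherenceMap:
    """Coherence between x and y after conditioning on z.

    Bins where the conditioning signal has zero power fall back to ordinary
    coherence; partial auto-spectra that go (numerically) nonpositive clip
    the estimate to 0.
    """
    if not est.has_z:
        raise ValueError("estimate carries no conditioning (z) spectra")
    if est.n_trials < 3:
        raise ValueError("partial coherence needs at least 3 trials")
    szz = est.auto_z[None, :]
    sxz = est.cross_xz
    szy = est.cross_zy[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(szz > 0, 1.0 / np.where(szz > 0, szz, 1.0), 0.0)
    s_xy_z = est.cross_xy - sxz * szy * inv
    s_xx_z = est.auto_x - (np.abs(sxz) ** 2) * inv
    s_yy_z = est.auto_y[None, :] - (np.abs(szy) ** 2) * inv
    vals = _safe_ratio(s_xy_z, np.maximum(s_xx_z, 0.0) * np.maximum(s_yy_z, 0.0))
    return CoherenceMap(vals, freqs=est.freqs, channel_names=est.channel_names,
                        kind="partial_coherence", n_trials=est.n_trials)


def fit_one_over_f(power: np.ndarray, freqs: np.ndarray):
    """Least-squares line through (log f, log P): the aperiodic 1/f profile.

    Returns ``(slope, intercept, residuals)`` with residuals on the log-power
    scale; peaks above the aperiodic trend (e.g. the 2-8 Hz syllable-rate
    bump of speech envelopes) appear as positive residuals.
    """
    power = np.asarray(power, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if power.shape != freqs.shape or power.ndim != 1:
        raise ValueError("power and freqs must be matching 1-D arrays")
    if np.any(power <= 0) or np.any(freqs <= 0):
        raise ValueError("power and freqs must be strictly positive")
    lf, lp = np.log10(freqs), np.log10(power)
    slope, intercept = np.polyfit(lf, lp, 1)
    residuals = lp - (slope * lf + intercept)
    return float(slope), float(intercept), residuals
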