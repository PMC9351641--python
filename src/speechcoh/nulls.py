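"""Permutation null baselines and trial subsampling.

Chance-level coherence between neural recordings and speech envelopes is
estimated by re-pairing neural trials with envelope trials from *other*
trials (a derangement: no trial keeps its original partner), computing the
coherence map for each of ``n_perm`` random re-pairings and averaging.
The observed-minus-permuted difference is approximately normal, no longer
bounded below by the coherence floor, and zero-centered when neural and
stimulus signals are unrelated — the statistic all group-level tests use.

For partial-coherence baselines the auditory and visual envelope streams
are re-paired with the *same* derangement, so the mutual audio-visual
coherence structure of the stimuli is preserved under the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import EpochedRecording
from .spectral import CoherenceMap, _safe_ratio

__all__ = [
    "sample_derangement",
    "permuted_baseline",
    "coherence_with_baseline",
    "envelope_coherence_test",
    "EnvelopeCoherenceTest",
    "subsample_estimate",
]


def sample_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random derangement of ``range(n)`` by rejection sampling."""
    if n < 2:
        raise ValueError("derangements need n >= 2")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def _as_trials(neural) -> tuple[np.ndarray, list[str]]:
    if isinstance(neural, EpochedRecording):
        return neural.data, list(neural.channel_names)
    x = np.asarray(neural, dtype=float)
    if x.ndim == 2:
        x = x[:, None, :]
    return x, [f"ch{i:02d}" for i in range(x.shape[1])]


def _grid_bins(fs: float, n_samples: int, freq_grid: np.ndarray) -> np.ndarray:
    grid = np.atleast_1d(np.asarray(freq_grid, dtype=float))
    df = fs / n_samples
    if np.any(grid <= 0) or np.any(grid >= fs / 2):
        raise ValueError("freq_grid must lie strictly inside (0, fs/2)")
    bins = np.round(grid / df).astype(int)
    if len(np.unique(bins)) != len(bins):
        raise ValueError("frequency grid finer than native resolution")
    return bins


def _ffts(x: np.ndarray, y: np.ndarray, z: np.ndarray | None,
          fs: float, freq_grid: np.ndarray):
    n_samples = x.shape[-1]
    bins = _grid_bins(fs, n_samples, freq_grid)
    taper = np.hanning(n_samples)
    X = np.fft.rfft(x * taper, axis=-1)[..., bins]
    Y = np.fft.rfft(y * taper, axis=-1)[..., bins]
    Z = None if z is None else np.fft.rfft(z * taper, axis=-1)[..., bins]
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)[bins]
    return X, Y, Z, freqs


def _map_from_ffts(X, Y, Z, idx_x, idx_y, kind: str) -> np.ndarray:
    """Coherence or partial-coherence values for a given trial pairing.

    ``idx_x``/``idx_y`` select and order the trials entering the average;
    Z (when present) is re-paired together with Y.
    """
    Xs, Ys = X[idx_x], Y[idx_y]
    auto_x = np.mean(np.abs(Xs) ** 2, axis=0)
    auto_y = np.mean(np.abs(Ys) ** 2, axis=0)
    cross_xy = np.mean(Xs * np.conj(Ys)[:, None, :], axis=0)
    if kind == "coherence":
        return _safe_ratio(cross_xy, auto_x * auto_y[None, :])
    Zs = Z[idx_y]
    auto_z = np.mean(np.abs(Zs) ** 2, axis=0)[None, :]
    cross_xz = np.mean(Xs * np.conj(Zs)[:, None, :], axis=0)
    cross_zy = np.mean(Zs * np.conj(Ys), axis=0)[None, :]
    inv = np.where(auto_z > 0, 1.0 / np.where(auto_z > 0, auto_z, 1.0), 0.0)
    s_xy = cross_xy - cross_xz * cross_zy * inv
    s_xx = auto_x - (np.abs(cross_xz) ** 2) * inv
    s_yy = auto_y[None, :] - (np.abs(cross_zy) ** 2) * inv
    return _safe_ratio(s_xy, np.maximum(s_xx, 0.0) * np.maximum(s_yy, 0.0))


def _check_estimator(estimator: str, z_trials) -> None:
    if estimator not in ("coherence", "partial_coherence"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if estimator == "partial_coherence" and z_trials is None:
        raise ValueError("partial_coherence requires z_trials")


def permuted_baseline(
    neural,
    env_trials: np.ndarray,
    fs: float,
    freq_grid: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
    z_trials: np.ndarray | None = None,
    estimator: str = "coherence",
) -> CoherenceMap:
    """Average coherence map over ``n_perm`` deranged trial re-pairings."""
    _check_estimator(estimator, z_trials)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x, names = _as_trials(neural)
    y = np.asarray(env_trials, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("permutation baseline needs at least 2 trials")
    if n == 2:
        warnings.warn("only one derangement exists for 2 trials; baseline has no variety")
    if y.shape[0] != n or y.shape[-1] != x.shape[-1]:
        raise ValueError("envelope trials must match neural trials in count and length")
    z = None if z_trials is None else np.asarray(z_trials, dtype=float)
    X, Y, Z, freqs = _ffts(x, y, z, fs, freq_grid)
    rng = np.random.default_rng(seed)
    idx_x = np.arange(n)
    acc = np.zeros((x.shape[1], freqs.size))
    kind = estimator
    for _ in range(n_perm):
        perm = sample_derangement(n, rng)
        acc += _map_from_ffts(X, Y, Z, idx_x, perm, kind)
    return CoherenceMap(acc / n_perm, freqs=freqs, channel_names=names,
                        kind=kind, n_trials=n)


def coherence_with_baseline(
    neural,
    env_trials: np.ndarray,
    fs: float,
    freq_grid: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
    z_trials: np.ndarray | None = None,
    estimator: str = "coherence",
) -> CoherenceMap:
    """Observed coherence map with its permuted baseline attached."""
    _check_estimator(estimator, z_trials)
    x, names = _as_trials(neural)
    y = np.asarray(env_trials, dtype=float)
    z = None if z_trials is None else np.asarray(z_trials, dtype=float)
    X, Y, Z, freqs = _ffts(x, y, z, fs, freq_grid)
    idx = np.arange(x.shape[0])
    observed = _map_from_ffts(X, Y, Z, idx, idx, estimator)
    base = permuted_baseline(neural, env_trials, fs, freq_grid, n_perm=n_perm,
                             seed=seed, z_trials=z_trials, estimator=estimator)
    return CoherenceMap(observed, freqs=freqs, channel_names=names,
                        kind=estimator, n_trials=x.shape[0], baseline=base.values)


@dataclass
class EnvelopeCoherenceTest:
    """Per-frequency stimulus coherence with permutation p-values."""

    freqs: np.ndarray
    coherence: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    alpha: float
    n_perm: int


def envelope_coherence_test(
    aud_set: np.ndarray,
    vis_set: np.ndarray,
    fs: float,
    freq_grid: np.ndarray | None = None,
    n_perm: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
) -> EnvelopeCoherenceTest:
    """Test at which frequencies the auditory and visual envelope sets cohere.

    Observed coherence is computed across the paired stimulus sets; the
    null re-pairs the visual set with a random permutation of the auditory
    set ``n_perm`` times.  One-tailed p-values use the add-one convention
    ``p = (#permuted >= observed + 1) / (n_perm + 1)`` and the significance
    mask applies a Bonferroni correction over frequencies at ``alpha``.
    """
    a = np.asarray(aud_set, dtype=float)
    v = np.asarray(vis_set, dtype=float)
    if a.shape != v.shape or a.ndim != 2:
        raise ValueError("aud_set and vis_set must be matching (trials, samples) arrays")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired stimuli")
    if np.any(np.std(a, axis=-1) == 0) or np.any(np.std(v, axis=-1) == 0):
        raise ValueError("degenerate constant signals in the stimulus sets")
    if freq_grid is None:
        freq_grid = np.arange(0.5, 20.0 + 1e-9, 0.5)
    A, V, _, freqs = _ffts(a[:, None, :], v, None, fs, freq_grid)
    A = A[:, 0, :]
    auto_a = np.mean(np.abs(A) ** 2, axis=0)
    auto_v = np.mean(np.abs(V) ** 2, axis=0)
    denom = auto_a * auto_v
    observed = _safe_ratio(np.mean(A * np.conj(V), axis=0), denom)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(freqs.size)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        permuted = _safe_ratio(np.mean(A[perm] * np.conj(V), axis=0), denom)
        exceed += permuted >= observed
    p = (exceed + 1.0) / (n_perm + 1.0)
    sig = p < alpha / freqs.size
    return EnvelopeCoherenceTest(freqs=freqs, coherence=observed, p_values=p,
                                 significant=sig, alpha=alpha, n_perm=n_perm)


def subsample_estimate(
    neural,
    env_trials: np.ndarray,
    fs: float,
    freq_grid: np.ndarray,
    n_target: int,
    n_rep: int = 100,
    seed: int = 0,
    z_trials: np.ndarray | None = None,
    estimator: str = "coherence",
) -> CoherenceMap:
    """Average estimator over ``n_rep`` random trial subsets of size ``n_target``.

    Used to compare conditions with unequal trial counts without biasing
    the coherence estimate by its trial-count dependence: the abundant
    condition is repeatedly subsampled (without replacement) down to the
    scarcer condition's count and the maps averaged.
    """
    _check_estimator(estimator, z_trials)
    if n_target < 3:
        raise ValueError("n_target must be >= 3")
    x, names = _as_trials(neural)
    y = np.asarray(env_trials, dtype=float)
    n = x.shape[0]
    if n_target > n:
        raise ValueError(f"n_target={n_target} exceeds available trials {n}")
    z = None if z_trials is None else np.asarray(z_trials, dtype=float)
    X, Y, Z, freqs = _ffts(x, y, z, fs, freq_grid)
    rng = np.random.default_rng(seed)
    acc = np.zeros((x.shape[1], freqs.size))
    for _ in range(n_rep):
        idx = rng.choice(n, size=n_target, replace=False)
        acc += _map_from_ffts(X, Y, Z, idx, idx, estimator)
    return CoherenceMap(acc / n_rep, freqs=freqs, channel_names=names,
                        kind=estimator, n_trials=n_target)
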