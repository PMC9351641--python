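"""Group-level cluster-based permutation tests and ROI contrasts.

The subject-level input is a true-minus-permuted coherence map per subject
(subjects x channels x frequencies).  A one-sample t statistic is computed
per channel-frequency cell; cells exceeding the cluster-defining threshold
are grouped into clusters connected through the channel adjacency graph
(within a frequency) and across neighbouring frequency bins (within a
channel).  Cluster mass is the summed t, and the familywise-corrected
p-value of each cluster comes from the permutation distribution of the
*maximum* cluster mass under random per-subject sign flips — the standard
exchangeability argument for a paired difference whose sign is arbitrary
under the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
import itertools
import json

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .spectral import CoherenceMap

__all__ = [
    "SubjectStatMap",
    "ClusterResult",
    "one_sample_cluster_test",
    "roi_average",
    "roi_contrast",
]


@dataclass
class SubjectStatMap:
    """Per-subject channel x frequency statistic maps with channel adjacency."""

    values: np.ndarray                 # (subjects, channels, freqs)
    adjacency: np.ndarray              # (channels, channels) bool, symmetric
    freqs: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be subjects x channels x freqs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("subject maps contain missing values")
        adj = np.asarray(self.adjacency, dtype=bool)
        n_ch = self.values.shape[1]
        if adj.shape != (n_ch, n_ch):
            raise ValueError("adjacency must be channels x channels")
        if not np.array_equal(adj, adj.T) or np.any(np.diag(adj)):
            raise ValueError("adjacency must be symmetric with empty diagonal")
        self.adjacency = adj
        self.freqs = np.asarray(self.freqs, dtype=float)
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(n_ch)]


@dataclass
class ClusterResult:
    """Clusters of supra-threshold cells with permutation p-values."""

    clusters: list[list[tuple[int, int]]]   # (channel, freq) index pairs
    masses: np.ndarray
    p_values: np.ndarray
    n_perm: int
    cdt: float                               # t threshold actually applied
    cdt_p: float
    t_map: np.ndarray
    alpha: float = 0.05

    @property
    def significant(self) -> list[int]:
        return [i for i, p in enumerate(self.p_values) if p < self.alpha]

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean channel x freq mask of cells in significant clusters."""
        out = np.zeros(shape, dtype=bool)
        for i in self.significant:
            for c, f in self.clusters[i]:
                out[c, f] = True
        return out

    def save(self, path: str | Path) -> None:
        payload = {
            "clusters": [[list(map(int, cell)) for cell in cl] for cl in self.clusters],
            "masses": [float(m) for m in self.masses],
            "p_values": [float(p) for p in self.p_values],
            "n_perm": int(self.n_perm),
            "cdt": float(self.cdt),
            "cdt_p": float(self.cdt_p),
            "alpha": float(self.alpha),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _cell_graph(adjacency: np.ndarray, n_freqs: int) -> sparse.csr_matrix:
    """Connectivity over flattened (channel, freq) cells.

    Cells are neighbours if they share a frequency bin and their channels
    are adjacent, or share a channel and sit in consecutive frequency bins.
    """
    n_ch = adjacency.shape[0]
    ch_graph = sparse.csr_matrix(adjacency)
    freq_graph = sparse.diags([np.ones(n_freqs - 1)] * 2, [-1, 1], format="csr") \
        if n_freqs > 1 else sparse.csr_matrix((1, 1))
    eye_f = sparse.identity(n_freqs, format="csr")
    eye_c = sparse.identity(n_ch, format="csr")
    return (sparse.kron(ch_graph, eye_f) + sparse.kron(eye_c, freq_graph)).tocsr()


def _t_per_cell(flat: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """One-sample t for every sign-flip row.

    ``flat`` is (subjects, cells); ``flips`` is (n, subjects) of +-1.  The
    sum of squares is flip-invariant, so each t map costs one matmul.
    """
    n = flat.shape[0]
    means = flips @ flat / n
    ss = np.sum(flat**2, axis=0)
    var = np.maximum(ss - n * means**2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    return np.where(var > 0, t, 0.0)


def _clusters_from_t(t_flat: np.ndarray, cdt: float, graph: sparse.csr_matrix):
    supra = np.flatnonzero(t_flat > cdt)
    if supra.size == 0:
        return [], np.empty(0)
    sub = graph[supra][:, supra]
    n_comp, labels = connected_components(sub, directed=False)
    clusters = [supra[labels == k] for k in range(n_comp)]
    masses = np.array([t_flat[c].sum() for c in clusters])
    return clusters, masses


def one_sample_cluster_test(
    maps: SubjectStatMap,
    n_perm: int = 5000,
    cdt_p: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """One-sample (vs 0) cluster-based permutation test, positive tail.

    ``cdt_p`` is converted to a one-sided t quantile with n_subjects - 1
    degrees of freedom.  The null distribution is the maximum cluster mass
    over random per-subject sign flips; ``n_perm="all"`` enumerates all
    2^n flips exactly.  Cluster p-values use the add-one convention.
    """
    vals = maps.values
    n_sub, n_ch, n_fr = vals.shape
    if n_sub < 5 and n_perm != "all":
        raise ValueError("need at least 5 subjects")
    flat = vals.reshape(n_sub, n_ch * n_fr)
    if np.any(np.all(vals == 0, axis=0)):
        warnings.warn("constant-zero cells have undefined t; treated as sub-threshold")
    cdt = float(stats.t.ppf(1.0 - cdt_p, df=n_sub - 1))
    graph = _cell_graph(maps.adjacency, n_fr)

    t_obs = _t_per_cell(flat, np.ones((1, n_sub)))[0]
    clusters, masses = _clusters_from_t(t_obs, cdt, graph)

    if n_perm == "all":
        flips = np.array(list(itertools.product((1.0, -1.0), repeat=n_sub)))
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        flips = rng.choice([1.0, -1.0], size=(int(n_perm), n_sub))
    t_null = _t_per_cell(flat, flips)
    null_max = np.empty(flips.shape[0])
    for i in range(flips.shape[0]):
        _, m = _clusters_from_t(t_null[i], cdt, graph)
        null_max[i] = m.max() if m.size else 0.0

    n_eff = flips.shape[0]
    p_values = np.array([
        (np.sum(null_max >= m) + 1.0) / (n_eff + 1.0) for m in masses
    ])
    cluster_cells = [
        [(int(c // n_fr), int(c % n_fr)) for c in cl] for cl in clusters
    ]
    return ClusterResult(
        clusters=cluster_cells, masses=masses, p_values=p_values,
        n_perm=n_eff, cdt=cdt, cdt_p=cdt_p,
        t_map=t_obs.reshape(n_ch, n_fr), alpha=alpha,
    )


def roi_average(
    source,
    roi: list[str],
    band: tuple[float, float] = (2.0, 6.0),
    use_effect: bool = True,
) -> np.ndarray | float:
    """Mean over ROI channels and a frequency band.

    Accepts a :class:`CoherenceMap` (returns a scalar; the true-minus-
    baseline effect when a baseline is attached and ``use_effect``) or a
    :class:`SubjectStatMap` (returns one scalar per subject).
    """
    if not roi:
        raise ValueError("roi must be a nonempty channel label set")
    if isinstance(source, CoherenceMap):
        values = source.effect if (use_effect and source.baseline is not None) \
            else source.values
        names, freqs = source.channel_names, source.freqs
        axis_subjects = False
    elif isinstance(source, SubjectStatMap):
        values, names, freqs = source.values, source.channel_names, source.freqs
        axis_subjects = True
    else:
        raise TypeError("source must be a CoherenceMap or SubjectStatMap")
    idx = []
    for lab in roi:
        if lab not in names:
            raise KeyError(f"unknown channel label {lab!r}")
        idx.append(names.index(lab))
    fsel = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    if not np.any(fsel):
        raise ValueError(f"no frequencies inside band {band}")
    sel = values[..., idx, :][..., fsel]
    out = sel.mean(axis=(-2, -1))
    return out if axis_subjects else float(out)


def roi_contrast(a: np.ndarray, b: np.ndarray | float = 0.0, tail: str = "one"):
    """Paired t contrast of per-subject ROI scalars.

    ``b = 0`` tests above-baseline coherence (one-tailed by convention);
    two paired samples give a condition contrast.  Returns
    ``(t, p, mean_difference)``.
    """
    a = np.asarray(a, dtype=float)
    b_arr = np.broadcast_to(np.asarray(b, dtype=float), a.shape)
    if a.ndim != 1 or a.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    d = a - b_arr
    sd = np.std(d, ddof=1)
    if sd == 0:
        if np.all(d == 0):
            # no difference anywhere: t = 0 and no evidence against the null
            return 0.0, 1.0, 0.0
        raise ValueError("zero variance of paired differences; t undefined")
    t = float(np.mean(d) / (sd / np.sqrt(d.size)))
    df = d.size - 1
    p = float(stats.t.sf(t, df)) if tail == "one" else float(2 * stats.t.sf(abs(t), df))
    return t, p, float(np.mean(d))
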