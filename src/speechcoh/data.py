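"""Shared containers: epoched multichannel recordings and their I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = ["EpochedRecording"]


@dataclass
class EpochedRecording:
    """Epoched neural recording: trials x channels x samples.

    ``adjacency`` is a symmetric boolean channel-by-channel matrix with an
    empty diagonal, used by the cluster statistics to define spatial
    neighbours.  ``groups`` maps region labels (e.g. "STG", "occipital") to
    lists of channel names.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    condition: str = ""
    adjacency: np.ndarray | None = None
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length must match data")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.adjacency is not None:
            adj = np.asarray(self.adjacency, dtype=bool)
            if adj.shape != (self.n_channels, self.n_channels):
                raise ValueError("adjacency must be n_channels x n_channels")
            if not np.array_equal(adj, adj.T) or np.any(np.diag(adj)):
                raise ValueError("adjacency must be symmetric with empty diagonal")
            self.adjacency = adj

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_indices(self, labels: list[str]) -> np.ndarray:
        idx = []
        for lab in labels:
            if lab not in self.channel_names:
                raise KeyError(f"unknown channel {lab!r}")
            idx.append(self.channel_names.index(lab))
        return np.asarray(idx, dtype=int)

    def group_indices(self, group: str) -> np.ndarray:
        if group not in self.groups:
            raise KeyError(f"unknown channel group {group!r}")
        return self.channel_indices(self.groups[group])

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.attrs["fs"] = self.fs
            f.attrs["condition"] = self.condition
            f.create_dataset(
                "channel_names",
                data=np.array(self.channel_names, dtype=h5py.string_dtype()),
            )
            if self.adjacency is not None:
                f.create_dataset("adjacency", data=self.adjacency.astype(np.uint8))
            grp = f.create_group("groups")
            for name, chans in self.groups.items():
                grp.create_dataset(name, data=np.array(chans, dtype=h5py.string_dtype()))

    @classmethod
    def load(cls, path: str | Path) -> "EpochedRecording":
        with h5py.File(path, "r") as f:
            adjacency = f["adjacency"][()].astype(bool) if "adjacency" in f else None
            groups = {
                name: [s.decode() if isinstance(s, bytes) else str(s) for s in ds[()]]
                for name, ds in f["groups"].items()
            } if "groups" in f else {}
            names = [s.decode() if isinstance(s, bytes) else str(s)
                     for s in f["channel_names"][()]]
            return cls(
                data=f["data"][()],
                fs=float(f.attrs["fs"]),
                channel_names=names,
                condition=str(f.attrs.get("condition", "")),
                adjacency=adjacency,
                groups=groups,
            )
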