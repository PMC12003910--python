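"""Scalp montage: channel positions and a neighborhood graph.

The default montage is a 24-channel 10-20 subset (including the posterior
alpha cluster Pz, P3, P4, POz). Positions come from the standard 10-20
template bundled with MNE, projected to 2-D; adjacency is the Delaunay
triangulation of the projected positions, the conventional sensor-neighbor
definition for cluster-based statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

DEFAULT_CHANNELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC1", "FC2", "T7", "C3", "Cz", "C4", "T8",
    "CP1", "CP2", "P7", "P3", "Pz", "P4", "P8",
    "POz", "O1", "O2",
)

#: Electrodes of the posterior alpha cluster.
PARIETAL_CLUSTER = ("Pz", "P3", "P4", "POz")


@dataclass(frozen=True)
class Montage:
    """Channel labels, 2-D scalp coordinates, and symmetric adjacency."""

    ch_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2)
    adjacency: frozenset[frozenset[str]]  # pairs of neighboring channels

    def __post_init__(self) -> None:
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        if self.positions.shape != (len(self.ch_names), 2):
            raise ValueError("positions must be (n_channels, 2)")
        names = set(self.ch_names)
        for pair in self.adjacency:
            if len(pair) != 2 or not pair <= names:
                raise ValueError(f"bad adjacency pair {set(pair)}")

    def require(self, channels=PARIETAL_CLUSTER) -> None:
        missing = [c for c in channels if c not in self.ch_names]
        if missing:
            raise ValueError(f"montage lacks required channels {missing}")

    def neighbors(self, ch: str) -> set[str]:
        return {
            other
            for pair in self.adjacency
            if ch in pair
            for other in pair
            if other != ch
        }

    def index(self, ch: str) -> int:
        return self.ch_names.index(ch)

    def adjacency_lists(self) -> list[list[int]]:
        """Index-based neighbor lists, for the permutation-cluster routines."""
        idx = {c: i for i, c in enumerate(self.ch_names)}
        out: list[list[int]] = [[] for _ in self.ch_names]
        for pair in self.adjacency:
            a, b = tuple(pair)
            out[idx[a]].append(idx[b])
            out[idx[b]].append(idx[a])
        return [sorted(n) for n in out]

    def to_yaml(self, path) -> None:
        payload = {
            "channels": [
                {"name": c, "x": float(x), "y": float(y)}
                for c, (x, y) in zip(self.ch_names, self.positions)
            ],
            "adjacency": sorted(sorted(pair) for pair in self.adjacency),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Montage":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        names = tuple(c["name"] for c in payload["channels"])
        pos = np.array([[c["x"], c["y"]] for c in payload["channels"]], dtype=float)
        adj = frozenset(frozenset(p) for p in payload["adjacency"])
        return cls(names, pos, adj)


def _delaunay_adjacency(
    ch_names: tuple[str, ...], positions: np.ndarray
) -> frozenset[frozenset[str]]:
    from scipy.spatial import Delaunay

    tri = Delaunay(positions)
    pairs: set[frozenset[str]] = set()
    for simplex in tri.simplices:
        for i in range(3):
            for j in range(i + 1, 3):
                pairs.add(frozenset((ch_names[simplex[i]], ch_names[simplex[j]])))
    return frozenset(pairs)


def default_montage(channels: tuple[str, ...] = DEFAULT_CHANNELS) -> Montage:
    """Build the default montage from MNE's standard 10-20 template."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage("standard_1020")
    ch_pos = std.get_positions()["ch_pos"]
    pos3d = np.array([ch_pos[c] for c in channels])
    # azimuthal-equidistant projection to 2-D (x right, y anterior)
    xyz = pos3d / np.linalg.norm(pos3d, axis=1, keepdims=True)
    theta = np.arccos(np.clip(xyz[:, 2], -1, 1))
    phi = np.arctan2(xyz[:, 1], xyz[:, 0])
    pos2d = np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])
    return Montage(tuple(channels), pos2d, _delaunay_adjacency(tuple(channels), pos2d))
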