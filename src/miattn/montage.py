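"""Standard 10/20 electrode geometry: 2-D positions and adjacency.

Positions come from the standard 10/05 template montage, projected to the
plane with an azimuthal-equidistant map (vertex at the origin).  Adjacency
is the Delaunay triangulation of the projected sites with edges longer
than 1.8x the median pruned, which keeps physical neighbours (e.g. F4-FC4)
connected without spanning the scalp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import Delaunay


@lru_cache(maxsize=4)
def _template_positions() -> dict:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mon = mne.channels.make_standard_montage("standard_1020")
    return mon.get_positions()["ch_pos"]


def positions_2d(labels: tuple[str, ...]) -> np.ndarray:
    """Azimuthal-equidistant scalp projection, (n, 2), vertex at origin."""
    pos = _template_positions()
    missing = [l for l in labels if l not in pos]
    if missing:
        raise KeyError(f"no template coordinates for {missing}")
    p = np.array([pos[l] for l in labels], dtype=float)
    r = np.linalg.norm(p, axis=1)
    theta = np.arccos(np.clip(p[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(p[:, 1], p[:, 0])
    return np.c_[theta * np.cos(phi), theta * np.sin(phi)]


@dataclass
class Adjacency:
    """Electrode neighbourhood graph as an inspectable edge list + matrix."""

    labels: tuple[str, ...]
    matrix: np.ndarray  # boolean, symmetric, zero diagonal

    @property
    def edges(self) -> list[tuple[str, str]]:
        i, j = np.nonzero(np.triu(self.matrix, 1))
        return [(self.labels[a], self.labels[b]) for a, b in zip(i, j)]

    def neighbors(self, label: str) -> list[str]:
        k = self.labels.index(label)
        return [self.labels[i] for i in np.flatnonzero(self.matrix[k])]


def electrode_adjacency(labels: tuple[str, ...],
                        prune_factor: float = 1.8) -> Adjacency:
    """Delaunay adjacency of the projected montage, long edges pruned."""
    labels = tuple(labels)
    xy = positions_2d(labels)
    tri = Delaunay(xy)
    n = len(labels)
    mat = np.zeros((n, n), dtype=bool)
    edges = set()
    for simplex in tri.simplices:
        for k in range(3):
            a, b = sorted((simplex[k], simplex[(k + 1) % 3]))
            edges.add((a, b))
    lengths = {e: float(np.linalg.norm(xy[e[0]] - xy[e[1]])) for e in edges}
    cutoff = prune_factor * float(np.median(list(lengths.values())))
    for (a, b), d in lengths.items():
        if d <= cutoff:
            mat[a, b] = mat[b, a] = True
    return Adjacency(labels, mat)
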