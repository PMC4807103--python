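"""Electrode montages on a spherical scalp.

Coordinate convention (normalized head units, scalp radius = ``head_radius``):
+x right, +y anterior (nasion), +z up (vertex).  Electrodes are laid out
quasi-uniformly on the upper spherical cap with a Fibonacci spiral, which
reproduces the coverage of a dense geodesic net without depending on any
proprietary sensor geometry.

The montage carries the two structures every downstream statistic needs:

* a symmetric nearest-neighbour adjacency graph ("contiguous electrodes"), and
* the nine named scalp clusters — anterior/central/posterior crossed with
  left/midline/right (AL, AM, AR, CL, CM, CR, PL, PM, PR) — that partition the
  montage into the regions used by the spatial persistence criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["Montage", "build_montage", "read_sfp", "write_sfp", "CLUSTER_NAMES"]

#: Nine scalp regions: (anterior|central|posterior) x (left|midline|right).
CLUSTER_NAMES = ("AL", "AM", "AR", "CL", "CM", "CR", "PL", "PM", "PR")

#: Polar half-angle of the electrode cap, radians.  2π/3 (120°) covers the
#: scalp down to below the ears, as dense EEG nets do after the artifact-prone
#: outermost belt has been removed.
CAP_HALF_ANGLE = 2.0 * np.pi / 3.0

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class Montage:
    """Electrode identities, positions on the scalp sphere, adjacency, clusters.

    Attributes
    ----------
    labels : list of str
        Electrode names, e.g. ``e1`` .. ``e110``.
    positions : ndarray, shape (n_channels, 3)
        Cartesian positions; every row has norm ``head_radius``.
    neighbors : tuple of tuple of int
        Symmetric adjacency lists (indices into ``labels``).
    clusters : dict
        Cluster name -> sorted tuple of electrode indices.  The nine clusters
        partition the montage.
    head_radius : float
        Scalp sphere radius in normalized head units.
    """

    labels: list[str]
    positions: np.ndarray
    neighbors: tuple[tuple[int, ...], ...]
    clusters: dict[str, tuple[int, ...]] = field(default_factory=dict)
    head_radius: float = 1.0

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def cluster_of(self) -> np.ndarray:
        """Cluster name per electrode, as an array of strings."""
        out = np.empty(self.n_channels, dtype=object)
        for name, idx in self.clusters.items():
            for i in idx:
                out[i] = name
        return out

    def adjacency_matrix(self) -> np.ndarray:
        """Dense boolean adjacency matrix (symmetric, zero diagonal)."""
        n = self.n_channels
        adj = np.zeros((n, n), dtype=bool)
        for i, nbrs in enumerate(self.neighbors):
            adj[i, list(nbrs)] = True
        return adj | adj.T


def _fibonacci_cap(n: int, half_angle: float) -> np.ndarray:
    """Quasi-uniform unit vectors on the spherical cap of given half-angle."""
    i = np.arange(n)
    # Equal-area spacing in z over the cap, vertex first.
    z = 1.0 - (1.0 - np.cos(half_angle)) * (i + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    phi = i * _GOLDEN_ANGLE
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _assign_clusters(positions: np.ndarray) -> dict[str, tuple[int, ...]]:
    """Partition electrodes into the nine named regions by angular sector.

    Anterior/central/posterior by terciles of the anterior coordinate (y),
    then left/midline/right by terciles of the lateral coordinate (x) within
    each band.  Terciles guarantee nine non-empty clusters for n >= 9 and are
    insensitive to the cap's exact extent.
    """
    y = positions[:, 1]
    qy = np.quantile(y, [1 / 3, 2 / 3])
    band = np.where(y >= qy[1], "A", np.where(y >= qy[0], "C", "P"))
    clusters: dict[str, list[int]] = {name: [] for name in CLUSTER_NAMES}
    for b in ("A", "C", "P"):
        idx = np.flatnonzero(band == b)
        x = positions[idx, 0]
        qx = np.quantile(x, [1 / 3, 2 / 3])
        side = np.where(x <= qx[0], "L", np.where(x <= qx[1], "M", "R"))
        for i, s in zip(idx, side):
            clusters[b + s].append(int(i))
    return {k: tuple(sorted(v)) for k, v in clusters.items()}


def _knn_adjacency(positions: np.ndarray, k: int) -> tuple[tuple[int, ...], ...]:
    """Symmetrized k-nearest-neighbour graph over 3-D electrode positions."""
    tree = cKDTree(positions)
    _, nn = tree.query(positions, k=k + 1)  # first hit is the point itself
    pairs: set[tuple[int, int]] = set()
    for i, row in enumerate(nn):
        for j in row[1:]:
            pairs.add((min(i, int(j)), max(i, int(j))))
    adj: list[set[int]] = [set() for _ in range(len(positions))]
    for i, j in pairs:
        adj[i].add(j)
        adj[j].add(i)
    return tuple(tuple(sorted(s)) for s in adj)


def build_montage(
    n_channels: int = 110,
    head_radius: float = 1.0,
    *,
    n_neighbors: int = 6,
    cap_half_angle: float = CAP_HALF_ANGLE,
) -> Montage:
    """Build a quasi-uniform spherical-cap montage with clusters and adjacency.

    Parameters
    ----------
    n_channels : int
        Number of electrodes (>= 16).  110 matches a 128-channel geodesic net
        with its outermost belt removed.
    head_radius : float
        Scalp sphere radius (normalized head units).
    n_neighbors : int
        Neighbour count for the adjacency graph before symmetrization.
    cap_half_angle : float
        Polar extent of the electrode cap, radians.

    Raises
    ------
    ValueError
        If ``n_channels`` is too small to populate nine non-empty clusters.
    """
    if n_channels < 16:
        raise ValueError(
            f"n_channels={n_channels}: at least 16 electrodes are required to "
            "populate nine non-empty scalp clusters"
        )
    unit = _fibonacci_cap(n_channels, cap_half_angle)
    positions = head_radius * unit
    clusters = _assign_clusters(positions)
    if any(len(v) == 0 for v in clusters.values()):
        raise ValueError("montage does not populate all nine scalp clusters")
    labels = [f"e{i + 1}" for i in range(n_channels)]
    neighbors = _knn_adjacency(positions, k=min(n_neighbors, n_channels - 1))
    return Montage(
        labels=labels,
        positions=positions,
        neighbors=neighbors,
        clusters=clusters,
        head_radius=float(head_radius),
    )


def write_sfp(montage: Montage, path) -> None:
    """Write electrode positions as whitespace-delimited ``label x y z`` text."""
    with open(path, "w") as fh:
        for label, pos in zip(montage.labels, montage.positions):
            fh.write(f"{label} {pos[0]:.8f} {pos[1]:.8f} {pos[2]:.8f}\n")


def read_sfp(path, *, n_neighbors: int = 6) -> Montage:
    """Read an ``.sfp``-style position file and rebuild adjacency and clusters.

    The head radius is taken from the median electrode norm; positions are not
    rescaled.
    """
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
    positions = np.asarray(rows, dtype=float)
    if len(labels) < 9:
        raise ValueError("montage file has fewer than nine electrodes")
    radius = float(np.median(np.linalg.norm(positions, axis=1)))
    return Montage(
        labels=labels,
        positions=positions,
        neighbors=_knn_adjacency(positions, k=min(n_neighbors, len(labels) - 1)),
        clusters=_assign_clusters(positions),
        head_radius=radius,
    )
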