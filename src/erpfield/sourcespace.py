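"""Source grid inside the brain sphere and the lead-field operator.

The solution space is a regular cubic lattice of points strictly inside the
brain sphere, each carrying a free-orientation dipole (three Cartesian
components).  Contiguity between solution points — used both by the inverse
prior and by the cluster-extent threshold — is the 26-neighbourhood of the
lattice: points within sqrt(3) grid spacings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .headmodel import HeadModel, dipole_gain
from .montage import Montage

__all__ = ["SourceGrid", "LeadField", "build_source_grid", "compute_lead_field"]


@dataclass(frozen=True)
class SourceGrid:
    """Regular grid of solution points with lattice adjacency.

    Attributes
    ----------
    points : ndarray, shape (n_points, 3)
        Coordinates in normalized head units, strictly inside the brain sphere.
    spacing : float
        Lattice step.
    neighbors : tuple of tuple of int
        Symmetric 26-neighbourhood adjacency lists.
    """

    points: np.ndarray
    spacing: float
    neighbors: tuple[tuple[int, ...], ...]

    @property
    def n_points(self) -> int:
        return len(self.points)

    def nearest(self, pos) -> int:
        """Index of the grid point nearest to ``pos``."""
        return int(np.argmin(np.linalg.norm(self.points - np.asarray(pos), axis=1)))

    def to_table(self, values: np.ndarray | None = None) -> np.ndarray:
        """Point table ``x y z [value]`` for delimited-text export."""
        if values is None:
            return self.points.copy()
        return np.column_stack([self.points, np.asarray(values)])


def build_source_grid(
    head: HeadModel | None = None,
    n_points: int = 1000,
    *,
    margin: float = 0.05,
) -> SourceGrid:
    """Build a cubic source lattice of approximately ``n_points`` points.

    Parameters
    ----------
    head : HeadModel, optional
        Volume conductor; points stay inside ``brain_radius - margin``.
    n_points : int
        Target point count.  ~1000 is the desk-scale default; denser grids
        (e.g. 3001) are obtained by raising this number.
    margin : float
        Clearance between the outermost points and the brain-sphere surface,
        in head units.
    """
    head = head or HeadModel()
    r_max = head.brain_radius - margin
    if r_max <= 0:
        raise ValueError("margin leaves no room inside the brain sphere")
    # spacing from the sphere volume; iterate once to land near the target
    spacing = (4.0 / 3.0 * np.pi * r_max**3 / n_points) ** (1.0 / 3.0)
    for _ in range(8):
        half = int(np.floor(r_max / spacing))
        ax = spacing * np.arange(-half, half + 1)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        pts = pts[np.linalg.norm(pts, axis=1) <= r_max]
        if len(pts) == 0:
            spacing *= 0.8
            continue
        ratio = (len(pts) / n_points) ** (1.0 / 3.0)
        if 0.95 < ratio < 1.05:
            break
        spacing *= ratio
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=np.sqrt(3.0) * spacing * 1.001)
    adj: list[set[int]] = [set() for _ in range(len(pts))]
    for i, j in pairs:
        adj[i].add(j)
        adj[j].add(i)
    return SourceGrid(
        points=pts,
        spacing=float(spacing),
        neighbors=tuple(tuple(sorted(s)) for s in adj),
    )


@dataclass(frozen=True)
class LeadField:
    """Linear forward operator from source moments to scalp potentials.

    ``matrix`` has shape (n_channels, 3 * n_points) with point-major,
    orientation-minor column ordering; columns are average-referenced.
    """

    matrix: np.ndarray
    grid: SourceGrid
    montage: Montage
    head: HeadModel

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    def project(self, moments: np.ndarray) -> np.ndarray:
        """Scalp potentials of a source-moment field.

        Parameters
        ----------
        moments : ndarray, shape (n_points, 3) or (3*n_points,)

        Returns
        -------
        ndarray, shape (n_channels,)
        """
        return self.matrix @ np.asarray(moments).reshape(-1)


def compute_lead_field(
    grid: SourceGrid, montage: Montage, head: HeadModel | None = None
) -> LeadField:
    """Analytic multishell-sphere lead field for a grid/montage pair."""
    head = head or HeadModel()
    gain = dipole_gain(head, grid.points, montage.positions)  # (m, 3, e)
    matrix = gain.transpose(2, 0, 1).reshape(montage.n_channels, -1)
    return LeadField(matrix=matrix, grid=grid, montage=montage, head=head)
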