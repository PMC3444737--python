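"""Regular background mesh and Gauss quadrature for the weak-form integrals.

The background mesh is a regular grid of non-overlapping, equal-sized,
axis-aligned cells tiling the domain bounding box; it exists only to place
Gauss-Legendre quadrature points and is independent of the node cloud. Cells
straddling the domain boundary are handled by keeping inside points with their
full Gauss weights and dropping outside points — no weight renormalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from efgmep.errors import InvalidArgumentError
from efgmep.geometry import Domain

log = logging.getLogger(__name__)

__all__ = [
    "BackgroundMesh",
    "QuadratureSet",
    "build_background_mesh",
    "gauss_points",
    "suggested_points_per_axis",
]


@dataclass
class BackgroundMesh:
    """Regular grid of cells tiling a bounding box."""

    origin: np.ndarray       # (d,) mm
    cell_size: np.ndarray    # (d,) mm
    counts: np.ndarray       # (d,) cells per axis

    @property
    def dim(self) -> int:
        return self.origin.shape[0]

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.counts))

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.cell_size))


@dataclass
class QuadratureSet:
    """Gauss points of all cells, with Jacobian-scaled weights (struct of arrays).

    ``weights`` carry the global Jacobian (units mm^d); the weights of one
    cell sum to the cell volume. ``inside`` marks points inside the problem
    domain; only those contribute to assembly.
    """

    positions: np.ndarray    # (Q, d) mm
    weights: np.ndarray      # (Q,) mm^d
    cell_ids: np.ndarray     # (Q,)
    inside: np.ndarray       # (Q,) bool

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]


def build_background_mesh(domain: Domain, cells_per_axis) -> BackgroundMesh:
    """Mesh of ``cells_per_axis`` equal cells per axis exactly tiling the
    domain bounding box."""
    counts = np.atleast_1d(np.asarray(cells_per_axis, dtype=int))
    if counts.shape[0] == 1 and domain.dim > 1:
        counts = np.full(domain.dim, counts[0])
    if counts.shape[0] != domain.dim or np.any(counts < 1):
        raise InvalidArgumentError("cells_per_axis must be >= 1 per axis")
    lo = domain.bbox[:, 0]
    hi = domain.bbox[:, 1]
    return BackgroundMesh(origin=lo, cell_size=(hi - lo) / counts, counts=counts)


def gauss_points(
    mesh: BackgroundMesh, points_per_axis: int, domain: Domain
) -> QuadratureSet:
    """Tensor-product Gauss-Legendre points in every cell.

    ``points_per_axis`` must be in {1, 2, 3, 4}. The p-point rule integrates
    polynomials up to degree 2p-1 exactly on each cell.
    """
    if points_per_axis not in (1, 2, 3, 4):
        raise InvalidArgumentError("points_per_axis must be in {1, 2, 3, 4}")
    d = mesh.dim
    x1, w1 = np.polynomial.legendre.leggauss(points_per_axis)

    # reference-cell tensor product in [0,1]^d
    grids = np.meshgrid(*([x1] * d), indexing="ij")
    ref = 0.5 * (np.column_stack([g.ravel() for g in grids]) + 1.0)   # (p^d, d)
    wgrids = np.meshgrid(*([w1] * d), indexing="ij")
    wref = np.prod(np.column_stack([g.ravel() for g in wgrids]), axis=1) / 2.0**d

    # cell lower corners
    axes = [mesh.origin[k] + mesh.cell_size[k] * np.arange(mesh.counts[k]) for k in range(d)]
    cg = np.meshgrid(*axes, indexing="ij")
    corners = np.column_stack([g.ravel() for g in cg])                 # (C, d)

    pos = (corners[:, None, :] + ref[None, :, :] * mesh.cell_size).reshape(-1, d)
    wts = np.tile(wref * mesh.cell_volume, mesh.n_cells)
    cell_ids = np.repeat(np.arange(mesh.n_cells), ref.shape[0])
    inside = domain.inside(pos)
    return QuadratureSet(positions=pos, weights=wts, cell_ids=cell_ids, inside=inside)


def suggested_points_per_axis(avg_nodes_per_cell: float, dim: int) -> int:
    """Advisory quadrature order from the average node count per cell.

    Returns 2 for sparsely populated cells (<= 8 nodes) and 3 otherwise.
    Advisory only — experiments pin their order explicitly; the choice is
    logged so it is never applied silently.
    """
    if avg_nodes_per_cell <= 0:
        raise InvalidArgumentError("avg_nodes_per_cell must be > 0")
    p = 2 if avg_nodes_per_cell <= 8 else 3
    log.info(
        "suggested quadrature order %d points/axis for %.2f nodes/cell in %dD",
        p, avg_nodes_per_cell, dim,
    )
    return p
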