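"""Galerkin assembly of the sparse mass and stiffness matrices.

Semi-discrete weak form of the monodomain equation over the node cloud:

    M_ij = int_Omega phi_i phi_j dOmega,
    K_ij = int_Omega grad(phi_i)^T D grad(phi_j) dOmega,

evaluated by looping over the background-mesh Gauss points that lie inside
the problem domain: each inside point contributes its Jacobian-scaled weight
times the local outer products of shape values / gradients over the nodes
whose influence domains cover it. Outside points are skipped with no weight
renormalization. The zero-flux natural boundary condition is built into the
weak form (no surface term), so K annihilates constant fields.

Shape functions are evaluated once per quadrature point (batched over points
with equal neighbor counts) and scattered into COO triplets; duplicates are
summed on sparse construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from efgmep.anisotropy import DiffusionParams, tensor_field
from efgmep.errors import EmptyDomainError
from efgmep.geometry import Domain, FiberField, NodeCloud
from efgmep.mls import BasisKind, WeightKind, influence_radii, mls_shape_many
from efgmep.quadrature import BackgroundMesh, gauss_points

log = logging.getLogger(__name__)

__all__ = ["SystemMatrices", "assemble"]

_TRIPLET_FLUSH = 8_000_000  # cap on buffered COO entries before partial sums


@dataclass
class SystemMatrices:
    """Sparse symmetric mass matrix M (mm^d) and stiffness matrix K."""

    M: sp.csr_matrix
    K: sp.csr_matrix

    @property
    def n_nodes(self) -> int:
        return self.M.shape[0]

    def lumped_mass(self) -> np.ndarray:
        """Row-sum lumped diagonal of M."""
        return np.asarray(self.M.sum(axis=1)).ravel()

    def dump_matrix_market(self, path_m, path_k):
        import scipy.io as sio

        sio.mmwrite(path_m, self.M)
        sio.mmwrite(path_k, self.K)


class _TripletAccumulator:
    """Buffers COO triplets; duplicates are summed once on final build.

    Index arrays are kept in int32 to halve memory traffic; partial sums are
    taken only if the buffer exceeds ``_TRIPLET_FLUSH`` entries.
    """

    def __init__(self, n: int):
        self.n = n
        self.rows: list[np.ndarray] = []
        self.cols: list[np.ndarray] = []
        self.vals_m: list[np.ndarray] = []
        self.vals_k: list[np.ndarray] = []
        self.buffered = 0
        self.m_acc: sp.csr_matrix | None = None
        self.k_acc: sp.csr_matrix | None = None

    def add(self, rows, cols, vm, vk):
        self.rows.append(rows.astype(np.int32, copy=False))
        self.cols.append(cols.astype(np.int32, copy=False))
        self.vals_m.append(vm)
        self.vals_k.append(vk)
        self.buffered += rows.size
        if self.buffered >= _TRIPLET_FLUSH:
            self._merge()

    def _merge(self):
        if not self.rows:
            return
        r = np.concatenate(self.rows)
        c = np.concatenate(self.cols)
        m_new = sp.coo_matrix(
            (np.concatenate(self.vals_m), (r, c)), shape=(self.n, self.n)
        ).tocsr()
        k_new = sp.coo_matrix(
            (np.concatenate(self.vals_k), (r, c)), shape=(self.n, self.n)
        ).tocsr()
        self.m_acc = m_new if self.m_acc is None else self.m_acc + m_new
        self.k_acc = k_new if self.k_acc is None else self.k_acc + k_new
        self.rows, self.cols, self.vals_m, self.vals_k = [], [], [], []
        self.buffered = 0

    def build(self) -> tuple[sp.csr_matrix, sp.csr_matrix]:
        self._merge()
        if self.m_acc is None:
            self.m_acc = sp.csr_matrix((self.n, self.n))
            self.k_acc = sp.csr_matrix((self.n, self.n))
        self.m_acc.sum_duplicates()
        self.k_acc.sum_duplicates()
        return self.m_acc.tocsr(), self.k_acc.tocsr()


def _batched_tensors(
    fibers: FiberField, params: DiffusionParams, phi, idx, pts, cloud
) -> np.ndarray:
    """Diffusion tensors (g, d, d) from MLS-interpolated nodal fibers.

    Uses the rank-1 identity D = sigma_cf I + (sigma_f - sigma_cf) f f^T,
    which equals the rotated fiber-frame tensor for any unit fiber f.
    Cancelled interpolations (norm < 1e-6) fall back to the nearest
    contributing node's fiber.
    """
    g, n = idx.shape
    dim = pts.shape[1]
    nodal = fibers.vectors[idx]                       # (g, n, 3)
    f = np.einsum("gn,gnk->gk", phi, nodal)[:, :dim]
    nrm = np.linalg.norm(f, axis=1)
    bad = nrm < 1e-6
    if np.any(bad):
        log.warning(
            "fiber interpolation cancelled at %d quadrature points; "
            "using nearest node's fiber",
            int(bad.sum()),
        )
        d2 = np.einsum(
            "gnk,gnk->gn",
            cloud.positions[idx] - pts[:, None, :],
            cloud.positions[idx] - pts[:, None, :],
        )
        nearest = np.argmin(d2, axis=1)
        f[bad] = nodal[bad, nearest[bad], :dim]
        nrm = np.linalg.norm(f, axis=1)
    f = f / nrm[:, None]
    eye = np.eye(dim)
    return params.sigma_cf * eye[None] + (params.sigma_f - params.sigma_cf) * np.einsum(
        "gi,gj->gij", f, f
    )


def assemble(
    cloud: NodeCloud,
    fibers: FiberField | None,
    domain: Domain,
    mesh: BackgroundMesh,
    points_per_axis: int,
    d_max: float,
    weight_kind: WeightKind = WeightKind.CUBIC,
    basis: BasisKind = BasisKind.LINEAR,
    params: DiffusionParams | None = None,
    min_neighbors: int | None = None,
) -> SystemMatrices:
    """Assemble M and K over the inside quadrature points.

    ``params`` defaults to the isotropic unit tensor. The diffusion tensor at
    each quadrature point comes from the MLS-interpolated nodal fibers, or is
    the constant sigma * I when the medium is isotropic or no fiber field is
    given. ``min_neighbors`` requests a per-point neighbor floor above the
    basis size (radius-growth fallback at sparsely covered points), which
    keeps shape functions well-behaved near thin-geometry slivers.
    """
    if params is None:
        params = DiffusionParams(1.0, 1.0)
    n = cloud.n_nodes
    d = cloud.dim
    radii = influence_radii(cloud, d_max)
    quad = gauss_points(mesh, points_per_axis, domain)
    inside_idx = np.flatnonzero(quad.inside)
    if inside_idx.size == 0:
        raise EmptyDomainError("no quadrature point inside the problem domain")
    pts = quad.positions[inside_idx]
    wts = quad.weights[inside_idx]

    iso = fibers is None or fibers.isotropic or params.isotropic
    sigma_iso = params.sigma_f if params.isotropic else params.sigma_cf
    d_iso = sigma_iso * np.eye(d)

    batches, singles = mls_shape_many(
        pts, cloud, radii, weight_kind, basis, min_neighbors=min_neighbors
    )
    acc = _TripletAccumulator(n)

    for b in batches:
        g, nn = b.node_indices.shape
        w_q = wts[b.point_ids]
        if iso:
            kv = sigma_iso * np.einsum("gnd,gmd->gnm", b.dphi, b.dphi)
        else:
            tens = _batched_tensors(fibers, params, b.phi, b.node_indices, b.points, cloud)
            kv = np.einsum("gnd,gde,gme->gnm", b.dphi, tens, b.dphi)
        mv = np.einsum("gn,gm->gnm", b.phi, b.phi)
        rows = np.repeat(b.node_indices, nn, axis=1).ravel()
        cols = np.tile(b.node_indices, (1, nn)).ravel()
        acc.add(
            rows,
            cols,
            (w_q[:, None, None] * mv).ravel(),
            (w_q[:, None, None] * kv).ravel(),
        )

    for pid, se in singles:
        w_q = wts[pid]
        if iso:
            d_q = d_iso
        else:
            d_q = tensor_field(fibers, params, se, cloud)
        nn = se.node_indices.size
        acc.add(
            np.repeat(se.node_indices, nn),
            np.tile(se.node_indices, nn),
            (w_q * np.outer(se.phi, se.phi)).ravel(),
            (w_q * (se.dphi @ d_q @ se.dphi.T)).ravel(),
        )

    m_mat, k_mat = acc.build()
    return SystemMatrices(M=m_mat, K=k_mat)
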