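"""Conventional-method baselines: finite differences and linear finite elements.

These exist for head-to-head comparison with the meshfree Galerkin solver on
identical node sets, mirroring the verification studies: a second-order FDM
for the 1D cable, linear (1D) / bilinear (2D) Lagrange FEM assembled on the
lattice with the same Gauss quadrature as the meshfree runs.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from efgmep.assembly import SystemMatrices
from efgmep.errors import InvalidArgumentError

__all__ = [
    "fdm_laplacian_1d",
    "fem_matrices_1d",
    "fem_matrices_2d",
]


def fdm_laplacian_1d(n_nodes: int, h: float) -> sp.csr_matrix:
    """Second-order 1D finite-difference Laplacian with zero-flux ends.

    Returns L such that (L v)_i approximates v''(x_i); Neumann boundaries by
    ghost-node mirroring (v_{-1} = v_1).
    """
    if n_nodes < 3:
        raise InvalidArgumentError("need at least 3 nodes")
    main = np.full(n_nodes, -2.0)
    off = np.ones(n_nodes - 1)
    lap = sp.diags([off, main, off], [-1, 0, 1], format="lil")
    lap[0, 1] = 2.0
    lap[-1, -2] = 2.0
    return (lap / h**2).tocsr()


def fem_matrices_1d(n_nodes: int, h: float, sigma: float = 1.0) -> SystemMatrices:
    """Linear 1D FEM mass/stiffness on a uniform lattice (exact integration)."""
    if n_nodes < 2:
        raise InvalidArgumentError("need at least 2 nodes")
    e = np.ones(n_nodes - 1)
    m_main = np.zeros(n_nodes)
    m_main[:-1] += 2.0 * h / 6.0
    m_main[1:] += 2.0 * h / 6.0
    M = sp.diags([h / 6.0 * e, m_main, h / 6.0 * e], [-1, 0, 1], format="csr")
    k_main = np.zeros(n_nodes)
    k_main[:-1] += sigma / h
    k_main[1:] += sigma / h
    K = sp.diags([-sigma / h * e, k_main, -sigma / h * e], [-1, 0, 1], format="csr")
    return SystemMatrices(M=M.tocsr(), K=K.tocsr())


def _bilinear_element(hx: float, hy: float, points_per_axis: int, sigma: float):
    """4x4 element mass/stiffness for a bilinear quad, by Gauss quadrature."""
    x1, w1 = np.polynomial.legendre.leggauss(points_per_axis)
    me = np.zeros((4, 4))
    ke = np.zeros((4, 4))
    for xi, wx in zip(x1, w1):
        for eta, wy in zip(x1, w1):
            s, t = 0.5 * (xi + 1.0), 0.5 * (eta + 1.0)
            nvals = np.array(
                [(1 - s) * (1 - t), s * (1 - t), (1 - s) * t, s * t]
            )
            dn = np.array(
                [
                    [-(1 - t) / hx, -(1 - s) / hy],
                    [(1 - t) / hx, -s / hy],
                    [-t / hx, (1 - s) / hy],
                    [t / hx, s / hy],
                ]
            )
            jac = 0.25 * wx * wy * hx * hy
            me += jac * np.outer(nvals, nvals)
            ke += jac * sigma * (dn @ dn.T)
    return me, ke


def fem_matrices_2d(
    counts: tuple[int, int],
    spacing: tuple[float, float],
    sigma: float = 1.0,
    points_per_axis: int = 4,
) -> SystemMatrices:
    """Bilinear FEM mass/stiffness on an (nx x ny)-node lattice.

    Node ids follow lexicographic (ix * ny + iy) ordering, matching the
    regular-grid generator. The element matrices are identical for every
    cell, so assembly is a vectorized scatter.
    """
    nx, ny = counts
    hx, hy = spacing
    me, ke = _bilinear_element(hx, hy, points_per_axis, sigma)
    cx, cy = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="ij")
    base = (cx * ny + cy).ravel()                      # lower-left node id
    conn = np.stack([base, base + ny, base + 1, base + ny + 1], axis=1)  # (C, 4)
    # local order: (0,0), (1,0), (0,1), (1,1) to match _bilinear_element
    rows = np.repeat(conn, 4, axis=1).ravel()
    cols = np.tile(conn, (1, 4)).ravel()
    n = nx * ny
    M = sp.coo_matrix(
        (np.tile(me.ravel(), conn.shape[0]), (rows, cols)), shape=(n, n)
    ).tocsr()
    K = sp.coo_matrix(
        (np.tile(ke.ravel(), conn.shape[0]), (rows, cols)), shape=(n, n)
    ).tocsr()
    return SystemMatrices(M=M, K=K)
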