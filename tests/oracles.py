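"""Independent brute-force references used by several test modules.

These deliberately avoid the package's closed-form MLS implementation: the
shape function is obtained by directly solving the weighted least-squares
normal equations for the local polynomial fit, and derivatives by central
finite differences of that fit. The 1D mass/stiffness oracle integrates the
brute-force shape functions with a high-order Gauss rule per cell.
"""

from __future__ import annotations

import numpy as np

from efgmep.mls import BasisKind, WeightKind, basis_size, weight


def brute_phi(point, positions, radii_d_m, kind, basis):
    """MLS shape values at ``point`` by direct weighted least squares.

    For each node I inside the influence domain the fit u_h(x) = p(x)^T e
    minimizes sum w_I (p(x_I)^T e - u_I)^2; phi_I is the dependence of
    u_h(point) on u_I, obtained column by column from the unit vectors.
    """
    point = np.asarray(point, dtype=float).ravel()
    dist = np.linalg.norm(positions - point, axis=1)
    idx = np.flatnonzero(dist < radii_d_m)
    w, _ = weight(kind, dist[idx] / radii_d_m[idx])
    sw = np.sqrt(w)
    P = _monomials(positions[idx] - point, basis)
    p0 = np.zeros(P.shape[1])
    p0[0] = 1.0
    phi = np.empty(idx.size)
    A = (sw[:, None] * P)
    for col in range(idx.size):
        u = np.zeros(idx.size)
        u[col] = 1.0
        e, *_ = np.linalg.lstsq(A, sw * u, rcond=None)
        phi[col] = p0 @ e
    return idx, phi


def _monomials(X, basis):
    X = np.atleast_2d(X)
    n, d = X.shape
    cols = [np.ones(n)]
    cols.extend(X[:, k] for k in range(d))
    if BasisKind(basis) == BasisKind.QUADRATIC:
        cols.extend(X[:, k] ** 2 for k in range(d))
        for i in range(d):
            for j in range(i + 1, d):
                cols.append(X[:, i] * X[:, j])
    return np.column_stack(cols)


def brute_matrices_1d(positions, d_max, kind, basis, sigma=1.0, n_gauss=50):
    """Dense 1D mass/stiffness by integrating brute-force shape functions
    with ``n_gauss`` Gauss points per node interval; derivatives by central
    differences of the brute-force fit."""
    pos = np.asarray(positions, dtype=float).reshape(-1, 1)
    n = pos.shape[0]
    order = np.argsort(pos[:, 0])
    assert np.all(order == np.arange(n)), "positions must be sorted"
    nn = np.empty(n)
    for i in range(n):
        others = np.delete(pos[:, 0], i)
        nn[i] = np.min(np.abs(others - pos[i, 0]))
    d_m = d_max * nn
    x1, w1 = np.polynomial.legendre.leggauss(n_gauss)
    M = np.zeros((n, n))
    K = np.zeros((n, n))
    # 5-point central stencil: O(eps^4) truncation keeps the derivative
    # oracle well below the 1e-9 comparison tolerance
    eps0 = 2.5e-4 * np.min(nn)
    for a, b in zip(pos[:-1, 0], pos[1:, 0]):
        xs = 0.5 * (b - a) * x1 + 0.5 * (a + b)
        ws = 0.5 * (b - a) * w1
        for xq, wq in zip(xs, ws):
            idx, phi = brute_phi([xq], pos, d_m, kind, basis)
            eps = eps0
            while True:
                sets = [brute_phi([xq + s * eps], pos, d_m, kind, basis)
                        for s in (1, -1, 2, -2)]
                if all(np.array_equal(s[0], idx) for s in sets):
                    break
                eps *= 0.1  # stencil crossed a support edge; shrink
            (_, p1), (_, m1), (_, p2), (_, m2) = sets
            dphi = (-p2 + 8.0 * p1 - 8.0 * m1 + m2) / (12.0 * eps)
            M[np.ix_(idx, idx)] += wq * np.outer(phi, phi)
            K[np.ix_(idx, idx)] += wq * sigma * np.outer(dphi, dphi)
    return M, K
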