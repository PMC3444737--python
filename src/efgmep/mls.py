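"""Moving-least-squares shape functions with compactly supported weights.

At an evaluation point x the field is approximated by u_h(x) = p(x)^T e(x),
where p is a monomial basis (linear or quadratic) and the coefficients e
minimize the weighted residual J = sum_I w(r_I) [p(x_I)^T e - u_I]^2 over the
nodes I whose influence domain covers x. Solving dJ/de = 0 gives the shape
functions

    phi(x) = p(x)^T A^{-1} B,   A = P^T W P,   B = P^T W,

with W the diagonal of weight values. First spatial derivatives follow from
the product rule with (A^{-1})_{,k} = -A^{-1} A_{,k} A^{-1}.

The weight is a radial spline (cubic or quartic) of the normalized distance
r_I = ||x - x_I|| / d_mI, where d_mI = d_max * c_I is the influence radius of
node I and c_I its nearest-neighbor spacing. For numerical conditioning the
basis is evaluated in coordinates shifted to the evaluation point, which
leaves the shape functions mathematically unchanged.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from efgmep.errors import InvalidArgumentError, SingularMomentMatrixError
from efgmep.geometry import NodeCloud

log = logging.getLogger(__name__)

__all__ = [
    "WeightKind",
    "BasisKind",
    "InfluenceRadii",
    "ShapeEval",
    "ShapeBatch",
    "weight",
    "influence_radii",
    "neighbors",
    "mls_shape",
    "mls_shape_many",
]

COND_WARN_THRESHOLD = 1e12


class WeightKind(str, enum.Enum):
    CUBIC = "cubic"
    QUARTIC = "quartic"


class BasisKind(str, enum.Enum):
    LINEAR = "linear"
    QUADRATIC = "quadratic"


def basis_size(basis: BasisKind, dim: int) -> int:
    """Number of monomials m: linear -> 1+d; quadratic -> full degree-2 set."""
    if basis == BasisKind.LINEAR:
        return 1 + dim
    return 1 + dim + dim * (dim + 1) // 2


@dataclass
class InfluenceRadii:
    """Per-node influence radii d_mI = d_max * c_I (mm)."""

    d_m: np.ndarray
    c: np.ndarray
    d_max: float


@dataclass
class ShapeEval:
    """MLS shape functions and first derivatives at one evaluation point."""

    point: np.ndarray           # (d,)
    node_indices: np.ndarray    # (n,)
    phi: np.ndarray             # (n,)
    dphi: np.ndarray            # (n, d), units 1/mm


@dataclass
class ShapeBatch:
    """Shape evaluations for a group of points sharing a neighbor count n.

    Struct-of-arrays layout so assembly can use batched linear algebra:
    ``point_ids`` indexes back into the caller's point array.
    """

    point_ids: np.ndarray       # (g,)
    points: np.ndarray          # (g, d)
    node_indices: np.ndarray    # (g, n)
    phi: np.ndarray             # (g, n)
    dphi: np.ndarray            # (g, n, d)


def weight(kind: WeightKind, r):
    """Radial weight w(r) and derivative dw/dr for normalized distance r >= 0.

    Both splines have compact support on [0, 1]: w = dw/dr = 0 for r > 1.
    The cubic spline is C^2 at its interior seam r = 1/2.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InvalidArgumentError("normalized distance r must be >= 0")
    kind = WeightKind(kind)
    w = np.zeros_like(r)
    dw = np.zeros_like(r)
    if kind == WeightKind.CUBIC:
        lo = r <= 0.5
        hi = (r > 0.5) & (r <= 1.0)
        rl, rh = r[lo], r[hi]
        w[lo] = 2.0 / 3.0 - 4.0 * rl**2 + 4.0 * rl**3
        dw[lo] = -8.0 * rl + 12.0 * rl**2
        w[hi] = 4.0 / 3.0 - 4.0 * rh + 4.0 * rh**2 - 4.0 / 3.0 * rh**3
        dw[hi] = -4.0 + 8.0 * rh - 4.0 * rh**2
    else:
        lo = r <= 1.0
        rl = r[lo]
        w[lo] = 1.0 - 6.0 * rl**2 + 8.0 * rl**3 - 3.0 * rl**4
        dw[lo] = -12.0 * rl + 24.0 * rl**2 - 12.0 * rl**3
    if w.ndim == 0:
        return float(w), float(dw)
    return w, dw


def influence_radii(cloud: NodeCloud, d_max: float) -> InfluenceRadii:
    """Influence radii from nearest-neighbor spacings: d_mI = d_max * c_I.

    c_I is the distance from node I to its nearest other node, the simplest
    density-reflecting choice; d_max (recommended 1-3) scales it so that
    influence domains overlap and the moment matrix stays invertible.
    """
    if d_max <= 0:
        raise InvalidArgumentError("d_max must be > 0")
    c = cloud.nearest_neighbor_distances()
    return InfluenceRadii(d_m=d_max * c, c=c, d_max=float(d_max))


def neighbors(point, cloud: NodeCloud, radii: InfluenceRadii) -> np.ndarray:
    """Indices of nodes whose influence domain covers ``point``.

    Exactly the nodes I with ||point - x_I|| < d_mI, in ascending id order.
    """
    point = np.asarray(point, dtype=float).ravel()
    r_max = float(np.max(radii.d_m))
    cand = cloud.kdtree.query_ball_point(point, r_max)
    if not cand:
        return np.empty(0, dtype=int)
    cand = np.sort(np.asarray(cand, dtype=int))
    dist = np.linalg.norm(cloud.positions[cand] - point, axis=1)
    return cand[dist < radii.d_m[cand]]


def _basis_rows(X: np.ndarray, basis: BasisKind) -> np.ndarray:
    """Monomial matrix P with rows p(X_i) for shifted coordinates X (n, d).

    Monomial order: constants, linears, squares,
    then cross terms (3D: 1, x, y, z, x2, y2, z2, xy, xz, yz).
    """
    n, d = X.shape
    cols = [np.ones(n)]
    cols.extend(X[:, k] for k in range(d))
    if basis == BasisKind.QUADRATIC:
        cols.extend(X[:, k] ** 2 for k in range(d))
        for i in range(d):
            for j in range(i + 1, d):
                cols.append(X[:, i] * X[:, j])
    return np.column_stack(cols)


def _basis_at_origin(basis: BasisKind, dim: int):
    """p(0) and its gradient rows dp/dx_k(0) for the shifted basis."""
    m = basis_size(basis, dim)
    p0 = np.zeros(m)
    p0[0] = 1.0
    dp0 = np.zeros((dim, m))
    for k in range(dim):
        dp0[k, 1 + k] = 1.0
    return p0, dp0


def mls_shape(
    point,
    cloud: NodeCloud,
    radii: InfluenceRadii,
    kind: WeightKind = WeightKind.CUBIC,
    basis: BasisKind = BasisKind.LINEAR,
    check_condition: bool = False,
    min_neighbors: int | None = None,
) -> ShapeEval:
    """MLS shape function values and first derivatives at ``point``.

    If fewer than m nodes cover the point (or ``min_neighbors``, when given a
    larger floor is requested for robustness at sparsely covered points), or
    the moment matrix A is singular, the neighbor search radius about the
    point is enlarged by a factor 1.2 up to 8 times before
    :class:`SingularMomentMatrixError` is raised.

    The shape functions reproduce any field polynomial in the basis exactly
    (in particular sum(phi) = 1 and sum(phi * x_I) = point for linear bases).
    """
    point = np.asarray(point, dtype=float).ravel()
    kind = WeightKind(kind)
    basis = BasisKind(basis)
    dim = cloud.dim
    m = basis_size(basis, dim)
    need = max(m, min_neighbors or 0)

    idx = neighbors(point, cloud, radii)
    grow = 1.0
    for attempt in range(9):
        if idx.size >= need:
            try:
                return _mls_shape_from_neighbors(
                    point, cloud, radii, idx, kind, basis, grow, check_condition
                )
            except np.linalg.LinAlgError:
                pass
        if attempt == 8:
            break
        grow *= 1.2
        cand = np.sort(
            np.asarray(
                cloud.kdtree.query_ball_point(point, grow * float(np.max(radii.d_m))),
                dtype=int,
            )
        )
        dist = np.linalg.norm(cloud.positions[cand] - point, axis=1)
        idx = cand[dist < grow * radii.d_m[cand]]
    if idx.size >= m:
        # could not reach the requested neighbor floor but the basis is
        # solvable: fall back to what the maximal search found
        try:
            return _mls_shape_from_neighbors(
                point, cloud, radii, idx, kind, basis, grow, check_condition
            )
        except np.linalg.LinAlgError:
            pass
    raise SingularMomentMatrixError(
        f"singular MLS moment matrix at point {point} with {idx.size} neighbors "
        f"(need >= {m})",
        point=point,
        n_neighbors=int(idx.size),
    )


def _mls_shape_from_neighbors(
    point, cloud, radii, idx, kind, basis, grow, check_condition
) -> ShapeEval:
    dim = cloud.dim
    X = cloud.positions[idx] - point        # shifted node coordinates (n, d)
    d_m = grow * radii.d_m[idx]
    dist = np.linalg.norm(X, axis=1)
    r = dist / d_m
    w, dwdr = weight(kind, r)
    if np.count_nonzero(w) < basis_size(basis, dim):
        raise np.linalg.LinAlgError("not enough nodes with nonzero weight")
    # dr/dx_k at the evaluation point (x - x_I = -X)
    with np.errstate(invalid="ignore", divide="ignore"):
        drdx = -X / (dist[:, None] * d_m[:, None])
    drdx[dist == 0.0] = 0.0                 # dw/dr = 0 at r = 0 for both kinds
    dwdx = dwdr[:, None] * drdx             # (n, d)

    # normalize the shifted coordinates by the local support scale: a linear
    # reparametrization of the basis (identical shape functions) that keeps
    # the moment matrix well conditioned on fine spacings
    scale = float(np.mean(d_m))
    P = _basis_rows(X / scale, basis)       # (n, m)
    p0, dp0 = _basis_at_origin(basis, dim)
    dp0 = dp0 / scale

    # A^{-1}B and A^{-1}p0 via QR of sqrt(W) P: the triangular factor has
    # the square root of A's condition number, so the solve stays accurate
    # even where the weighted node geometry is nearly degenerate
    sw = np.sqrt(np.maximum(w, 0.0))  # clip -1e-16 roundoff at r ~ 1
    q, r_fac = np.linalg.qr(sw[:, None] * P, mode="reduced")
    rdiag = np.abs(np.diag(r_fac))
    if rdiag.min() <= 1e-13 * max(rdiag.max(), 1e-300):
        raise np.linalg.LinAlgError("numerically singular moment matrix")
    if check_condition:
        cond = (rdiag.max() / rdiag.min()) ** 2
        if cond > COND_WARN_THRESHOLD:
            warnings.warn(
                f"MLS moment matrix condition number {cond:.2e} at {point}",
                RuntimeWarning,
                stacklevel=3,
            )
    # G = A^{-1} B = R^{-1} Q^T sqrt(W); gamma = A^{-1} p0
    G = np.linalg.solve(r_fac, q.T * sw)
    gamma = np.linalg.solve(r_fac, np.linalg.solve(r_fac.T, p0))
    phi = p0 @ G                            # (n,)

    dphi = np.empty((idx.size, dim))
    for k in range(dim):
        wk = dwdx[:, k]
        Bk = (wk[:, None] * P).T            # (m, n)
        # A_{,k} G contracted without forming A_{,k}: P^T diag(wk) (P G)
        AkG = P.T @ (wk[:, None] * (P @ G))
        dphi[:, k] = dp0[k] @ G + gamma @ (Bk - AkG)
    return ShapeEval(point=point, node_indices=idx, phi=phi, dphi=dphi)


def _weight_batch(kind: WeightKind, r: np.ndarray):
    """Vectorized weight spline for arrays of any shape (r assumed >= 0)."""
    w = np.zeros_like(r)
    dw = np.zeros_like(r)
    if kind == WeightKind.CUBIC:
        lo = r <= 0.5
        hi = (r > 0.5) & (r <= 1.0)
        rl, rh = r[lo], r[hi]
        w[lo] = 2.0 / 3.0 - 4.0 * rl**2 + 4.0 * rl**3
        dw[lo] = -8.0 * rl + 12.0 * rl**2
        w[hi] = 4.0 / 3.0 - 4.0 * rh + 4.0 * rh**2 - 4.0 / 3.0 * rh**3
        dw[hi] = -4.0 + 8.0 * rh - 4.0 * rh**2
    else:
        lo = r <= 1.0
        rl = r[lo]
        w[lo] = 1.0 - 6.0 * rl**2 + 8.0 * rl**3 - 3.0 * rl**4
        dw[lo] = -12.0 * rl + 24.0 * rl**2 - 12.0 * rl**3
    return w, dw


def _basis_batch(X: np.ndarray, basis: BasisKind) -> np.ndarray:
    """Batched monomial rows for shifted coordinates X of shape (g, n, d)."""
    g, n, d = X.shape
    cols = [np.ones((g, n))]
    cols.extend(X[..., k] for k in range(d))
    if basis == BasisKind.QUADRATIC:
        cols.extend(X[..., k] ** 2 for k in range(d))
        for i in range(d):
            for j in range(i + 1, d):
                cols.append(X[..., i] * X[..., j])
    return np.stack(cols, axis=-1)  # (g, n, m)


def mls_shape_many(
    points: np.ndarray,
    cloud: NodeCloud,
    radii: InfluenceRadii,
    kind: WeightKind = WeightKind.CUBIC,
    basis: BasisKind = BasisKind.LINEAR,
    chunk: int = 4096,
    min_neighbors: int | None = None,
) -> tuple[list[ShapeBatch], list[tuple[int, ShapeEval]]]:
    """Batched MLS evaluation at many points.

    Neighbor lists are found in one spatial-index query; points are grouped
    by neighbor count and each group is evaluated with batched linear
    algebra. Points that cannot be handled in a batch (fewer than m
    neighbors, or a singular moment matrix in the group) fall back to the
    scalar :func:`mls_shape` path with its radius-enlargement policy, and are
    returned separately as (point_id, ShapeEval) pairs.
    """
    kind = WeightKind(kind)
    basis = BasisKind(basis)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    npts, dim = pts.shape
    m = basis_size(basis, dim)
    r_max = float(np.max(radii.d_m))

    raw = cloud.kdtree.query_ball_point(pts, r_max)
    lengths = np.fromiter((len(l) for l in raw), dtype=int, count=npts)
    if lengths.sum() == 0:
        flat = np.empty(0, dtype=int)
    else:
        flat = np.concatenate([np.asarray(l, dtype=int) for l in raw])
    seg = np.repeat(np.arange(npts), lengths)
    dist = np.linalg.norm(cloud.positions[flat] - pts[seg], axis=1)
    mask = dist < radii.d_m[flat]
    seg, flat = seg[mask], flat[mask]
    order = np.lexsort((flat, seg))
    seg, flat = seg[order], flat[order]
    counts = np.bincount(seg, minlength=npts)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])

    batches: list[ShapeBatch] = []
    singles: list[tuple[int, ShapeEval]] = []

    def do_single(pid: int):
        singles.append(
            (pid, mls_shape(pts[pid], cloud, radii, kind, basis,
                            min_neighbors=min_neighbors))
        )

    need = max(m, min_neighbors or 0)
    p0, dp0 = _basis_at_origin(basis, dim)
    for n in np.unique(counts):
        sel = np.flatnonzero(counts == n)
        if n < need:
            for pid in sel:
                do_single(int(pid))
            continue
        idx_mat = flat[starts[sel][:, None] + np.arange(n)[None, :]]  # (G, n)
        for c0 in range(0, sel.size, chunk):
            sl = slice(c0, c0 + chunk)
            pid = sel[sl]
            idx = idx_mat[sl]
            try:
                batches.append(
                    _mls_batch_math(pts[pid], pid, idx, cloud, radii, kind, basis, p0, dp0)
                )
            except np.linalg.LinAlgError:
                for q in pid:
                    do_single(int(q))
    return batches, singles


def _mls_batch_math(P_pts, pid, idx, cloud, radii, kind, basis, p0, dp0) -> ShapeBatch:
    g, n = idx.shape
    dim = cloud.dim
    X = cloud.positions[idx] - P_pts[:, None, :]          # (g, n, d)
    d_m = radii.d_m[idx]                                  # (g, n)
    dist = np.linalg.norm(X, axis=2)
    r = dist / d_m
    w, dwdr = _weight_batch(kind, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        drdx = -X / (dist * d_m)[..., None]
    drdx[dist == 0.0] = 0.0
    dwdx = dwdr[..., None] * drdx                         # (g, n, d)

    scale = np.mean(d_m, axis=1)                          # (g,) local support scale
    P = _basis_batch(X / scale[:, None, None], basis)     # (g, n, m)
    # A^{-1}B and A^{-1}p0 via batched QR of sqrt(W) P (see scalar path)
    sw = np.sqrt(np.maximum(w, 0.0))  # clip -1e-16 roundoff at r ~ 1
    q, r_fac = np.linalg.qr(sw[..., None] * P, mode="reduced")  # (g,n,m),(g,m,m)
    m = p0.size
    rdiag = np.abs(r_fac[:, np.arange(m), np.arange(m)])
    if np.any(rdiag.min(axis=1) <= 1e-13 * np.maximum(rdiag.max(axis=1), 1e-300)):
        # numerically singular system in the chunk: re-route through the
        # scalar path with its growth/condition policy
        raise np.linalg.LinAlgError("ill-conditioned batch")
    G = np.linalg.solve(r_fac, np.swapaxes(q, 1, 2) * sw[:, None, :])  # (g, m, n)
    gamma = np.linalg.solve(
        r_fac, np.linalg.solve(np.swapaxes(r_fac, 1, 2), np.broadcast_to(p0, (g, m))[..., None])
    )[..., 0]                                             # (g, m)
    phi = G[:, 0, :]                                      # p0 = e1
    if not np.all(np.isfinite(phi)) or np.abs(phi).max() > 1e8:
        raise np.linalg.LinAlgError("ill-conditioned batch")

    B_d = np.einsum("gnd,gnm->gdmn", dwdx, P)             # (g, d, m, n)
    A_d = np.einsum("gnd,gni,gnj->gdij", dwdx, P, P)      # (g, d, m, m)
    AdG = A_d @ G[:, None, :, :]                          # (g, d, m, n)
    corr = np.einsum("gm,gdmn->gdn", gamma, B_d - AdG)    # (g, d, n)
    dphi = np.swapaxes(
        G[:, 1 : 1 + dim, :] / scale[:, None, None] + corr, 1, 2
    )                                                     # (g, n, d)
    return ShapeBatch(
        point_ids=np.asarray(pid, dtype=int),
        points=P_pts,
        node_indices=idx,
        phi=phi,
        dphi=dphi,
    )
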