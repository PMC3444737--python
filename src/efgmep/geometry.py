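"""Meshfree particle representations: node clouds, fiber fields and domains.

The problem geometry is a cloud of unstructured sample nodes without any
predefined connectivity. Material anisotropy is attached to the nodes as a
per-node unit fiber vector. A :class:`Domain` is a membership predicate plus a
bounding box; it decides which background-mesh quadrature points contribute to
the weak-form integrals.

All coordinates are in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from efgmep.errors import CapacityError, DegenerateGeometryError, InvalidArgumentError

__all__ = [
    "NodeCloud",
    "FiberField",
    "Domain",
    "make_regular_grid",
    "make_irregular_cloud",
    "make_ventricle_shell",
    "assign_uniform_fibers",
    "assign_split_fibers",
    "read_node_file",
    "write_node_file",
]


@dataclass
class NodeCloud:
    """Positions of unstructured sample nodes.

    Parameters
    ----------
    positions : (N, d) float array
        Node coordinates in mm, d in {1, 2, 3}. Node ids are the row indices
        0..N-1.
    """

    positions: np.ndarray
    _tree: Optional[cKDTree] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.ndim != 2 or pos.shape[1] not in (1, 2, 3):
            raise InvalidArgumentError(
                f"positions must be (N, d) with d in 1..3, got shape {pos.shape}"
            )
        if not np.all(np.isfinite(pos)):
            raise InvalidArgumentError("node positions must be finite")
        self.positions = pos

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    @property
    def ids(self) -> np.ndarray:
        return np.arange(self.n_nodes)

    @property
    def kdtree(self) -> cKDTree:
        """Spatial index over the nodes, built lazily and cached."""
        if self._tree is None:
            self._tree = cKDTree(self.positions)
        return self._tree

    def nearest_neighbor_distances(self) -> np.ndarray:
        """Distance from each node to its nearest *other* node (mm)."""
        if self.n_nodes < 2:
            raise DegenerateGeometryError("need at least 2 nodes")
        d, _ = self.kdtree.query(self.positions, k=2)
        c = d[:, 1]
        if np.any(c <= 0.0):
            raise DegenerateGeometryError("coincident nodes in cloud")
        return c


@dataclass
class FiberField:
    """Per-node unit fiber vectors, or an isotropic flag.

    Fiber vectors are dimensionless direction cosines of Euclidean norm 1.
    ``isotropic=True`` means the medium has no preferred direction and
    ``vectors`` may be None.
    """

    vectors: Optional[np.ndarray] = None
    isotropic: bool = False

    def __post_init__(self):
        if self.isotropic:
            return
        if self.vectors is None:
            raise InvalidArgumentError("non-isotropic FiberField needs vectors")
        v = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        norms = np.linalg.norm(v, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise InvalidArgumentError("fiber vectors must be unit length (±1e-12)")
        self.vectors = v

    @property
    def n_nodes(self) -> int:
        return 0 if self.vectors is None else self.vectors.shape[0]


class Domain:
    """Geometric domain: a membership predicate plus its bounding box.

    Parameters
    ----------
    name : str
        Descriptive label echoed in reports.
    bbox : (d, 2) array-like
        Per-axis [lo, hi] bounds (mm) containing every inside point.
    inside_fn : callable, optional
        Vectorized predicate mapping (M, d) points to (M,) booleans. Defaults
        to the axis-aligned box test.
    """

    def __init__(self, name: str, bbox, inside_fn: Optional[Callable] = None):
        self.name = name
        self.bbox = np.atleast_2d(np.asarray(bbox, dtype=float))
        if self.bbox.shape[1] != 2 or np.any(self.bbox[:, 1] <= self.bbox[:, 0]):
            raise InvalidArgumentError("bbox must be per-axis [lo, hi] with hi > lo")
        self._inside_fn = inside_fn

    @property
    def dim(self) -> int:
        return self.bbox.shape[0]

    def inside(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        in_box = np.all(
            (pts >= self.bbox[:, 0] - 1e-12) & (pts <= self.bbox[:, 1] + 1e-12),
            axis=1,
        )
        if self._inside_fn is None:
            return in_box
        return in_box & np.asarray(self._inside_fn(pts), dtype=bool)

    def measure_bbox(self) -> float:
        return float(np.prod(self.bbox[:, 1] - self.bbox[:, 0]))


def make_regular_grid(bounds, counts) -> tuple[NodeCloud, Domain]:
    """Tensor-product lattice of nodes; the domain is the bounding box.

    Parameters
    ----------
    bounds : sequence of (lo, hi) pairs
        Per-axis interval in mm.
    counts : sequence of int
        Per-axis node counts, each >= 2. Lattice spacing per axis is
        (hi - lo) / (count - 1).
    """
    bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
    counts = np.atleast_1d(np.asarray(counts, dtype=int))
    if bounds.shape[0] != counts.shape[0]:
        raise InvalidArgumentError("bounds and counts must have the same length")
    if np.any(counts < 2):
        raise InvalidArgumentError("counts must be >= 2 per axis")
    if np.any(bounds[:, 1] <= bounds[:, 0]):
        raise InvalidArgumentError("degenerate bounds")
    axes = [np.linspace(lo, hi, c) for (lo, hi), c in zip(bounds, counts)]
    grids = np.meshgrid(*axes, indexing="ij")
    pos = np.column_stack([g.ravel() for g in grids])
    cloud = NodeCloud(pos)
    dom = Domain(f"box{tuple(int(c) for c in counts)}", bounds)
    return cloud, dom


def make_irregular_cloud(
    domain: Domain, n: int, min_spacing: float, seed: int
) -> NodeCloud:
    """Blue-noise-like cloud by dart throwing with a minimum spacing.

    Candidates are drawn uniformly in the bounding box, rejected if outside the
    domain or closer than ``min_spacing`` to an accepted node. Deterministic
    for a fixed seed. Raises :class:`CapacityError` (carrying the number of
    nodes placed) if ``n`` nodes cannot be placed within 1000*n attempts.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if min_spacing <= 0:
        raise InvalidArgumentError("min_spacing must be > 0")
    rng = np.random.default_rng(seed)
    lo, hi = domain.bbox[:, 0], domain.bbox[:, 1]
    accepted: list[np.ndarray] = []
    tree: Optional[cKDTree] = None
    pending: list[np.ndarray] = []  # accepted since last tree rebuild
    max_attempts = 1000 * n
    attempts = 0
    batch = max(64, n)
    while len(accepted) < n and attempts < max_attempts:
        cand = rng.uniform(lo, hi, size=(batch, domain.dim))
        ok = domain.inside(cand)
        for p in cand[ok]:
            if attempts >= max_attempts or len(accepted) >= n:
                break
            attempts += 1
            near = False
            if tree is not None and tree.query_ball_point(p, min_spacing):
                near = True
            if not near:
                for q in pending:
                    if np.dot(p - q, p - q) < min_spacing**2:
                        near = True
                        break
            if not near:
                accepted.append(p)
                pending.append(p)
                if len(pending) >= 64:
                    tree = cKDTree(np.asarray(accepted))
                    pending = []
        attempts += int(np.count_nonzero(~ok))
    if len(accepted) < n:
        raise CapacityError(
            f"placed only {len(accepted)}/{n} nodes with min_spacing="
            f"{min_spacing}; domain too tight",
            placed=len(accepted),
        )
    return NodeCloud(np.asarray(accepted))


def _shell_transmural_depth(pos: np.ndarray, endo: np.ndarray, epi: np.ndarray) -> np.ndarray:
    """Transmural coordinate t in [0, 1]: 0 on the endocardial ellipsoid,
    1 on the epicardial one, by interpolating the semi-axis family
    a(t) = a_endo + t (a_epi - a_endo) and solving the level condition."""
    pos = np.atleast_2d(pos)
    t = np.zeros(pos.shape[0])
    for i, p in enumerate(pos):
        # rho(t) = sum (p_k / a_k(t))^2 - 1 is strictly decreasing in t
        lo_t, hi_t = 0.0, 1.0
        for _ in range(60):
            mid = 0.5 * (lo_t + hi_t)
            a = endo + mid * (epi - endo)
            rho = np.sum((p / a) ** 2) - 1.0
            if rho > 0:
                lo_t = mid
            else:
                hi_t = mid
        t[i] = 0.5 * (lo_t + hi_t)
    return t


def make_ventricle_shell(
    epi_semi_axes=(30.0, 30.0, 45.0),
    endo_semi_axes=(20.0, 20.0, 37.0),
    base_height: float = 10.0,
    n: int = 3164,
    helix_angle_range=(-60.0, 60.0),
    seed: int = 0,
) -> tuple[NodeCloud, FiberField, Domain]:
    """Synthetic idealized left ventricle: a truncated prolate ellipsoid shell.

    This is a synthetic stand-in geometry: a thick shell between two coaxial
    ellipsoids (apex at -z), truncated at ``z = base_height``, filled with a
    blue-noise node cloud. Fibers lie in the local circumferential-longitudinal
    plane with a helix angle interpolated linearly from
    ``helix_angle_range[0]`` degrees on the endocardium to
    ``helix_angle_range[1]`` on the epicardium — the canonical rule-based
    idealized-LV fiber architecture.
    """
    epi = np.asarray(epi_semi_axes, dtype=float)
    endo = np.asarray(endo_semi_axes, dtype=float)
    if np.any(endo >= epi):
        raise InvalidArgumentError("endo semi-axes must be strictly inside epi")

    def inside_fn(pts):
        f_epi = np.sum((pts / epi) ** 2, axis=1)
        f_endo = np.sum((pts / endo) ** 2, axis=1)
        return (f_epi <= 1.0) & (f_endo >= 1.0) & (pts[:, 2] <= base_height)

    bbox = np.array([[-epi[0], epi[0]], [-epi[1], epi[1]], [-epi[2], base_height]])
    dom = Domain("ventricle_shell", bbox, inside_fn)

    # spacing targeting roughly n nodes in the shell volume
    cap = 1.0 - 0.0  # full shell below base_height; approximate truncation factor
    vol_full = 4.0 / 3.0 * np.pi * (np.prod(epi) - np.prod(endo))
    frac = 0.5 * (1.0 + base_height / epi[2])  # crude truncated fraction
    vol = vol_full * min(1.0, frac) * cap
    spacing = 0.7 * (vol / n) ** (1.0 / 3.0)
    cloud = make_irregular_cloud(dom, n, min_spacing=spacing, seed=seed)

    t = _shell_transmural_depth(cloud.positions, endo, epi)
    theta = np.deg2rad(
        helix_angle_range[0] + t * (helix_angle_range[1] - helix_angle_range[0])
    )
    vecs = np.empty((n, 3))
    for i, p in enumerate(cloud.positions):
        a = endo + t[i] * (epi - endo)
        normal = p / a**2
        nrm = np.linalg.norm(normal)
        normal = normal / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
        circ = np.array([-p[1], p[0], 0.0])
        cn = np.linalg.norm(circ)
        if cn < 1e-9:  # on the axis (near apex): direction is arbitrary
            circ = np.array([1.0, 0.0, 0.0])
        else:
            circ = circ / cn
        longi = np.array([0.0, 0.0, 1.0]) - normal[2] * normal
        ln = np.linalg.norm(longi)
        longi = longi / ln if ln > 1e-9 else np.cross(normal, circ)
        f = np.cos(theta[i]) * circ + np.sin(theta[i]) * longi
        vecs[i] = f / np.linalg.norm(f)
    return cloud, FiberField(vectors=vecs), dom


def _normalize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    nrm = np.linalg.norm(v)
    if nrm == 0.0:
        raise InvalidArgumentError("fiber direction must be nonzero")
    return v / nrm


def assign_uniform_fibers(cloud: NodeCloud, direction) -> FiberField:
    """Every node carries the (normalized) given direction."""
    d = _normalize(direction)
    return FiberField(vectors=np.tile(d, (cloud.n_nodes, 1)))


def assign_split_fibers(
    cloud: NodeCloud, plane_axis: int, plane_value: float, dir_a, dir_b
) -> FiberField:
    """Two fiber populations split by an axis-aligned plane.

    Nodes with coordinate[plane_axis] < plane_value get ``dir_a``, the rest
    ``dir_b`` (both normalized).
    """
    a = _normalize(dir_a)
    b = _normalize(dir_b)
    vecs = np.where(
        (cloud.positions[:, plane_axis] < plane_value)[:, None], a, b
    )
    return FiberField(vectors=vecs)


def write_node_file(path, cloud: NodeCloud, fibers: Optional[FiberField] = None):
    """Write the plain-text node table ``id x y z [fx fy fz]`` (mm, 0-based)."""
    pos = cloud.positions
    pad = np.zeros((cloud.n_nodes, 3 - cloud.dim))
    cols = [cloud.ids[:, None], pos, pad]
    header = "id x y z"
    if fibers is not None and not fibers.isotropic:
        cols.append(fibers.vectors)
        header += " fx fy fz"
    data = np.column_stack(cols)
    np.savetxt(path, data, header=header, fmt="%.17g")


def read_node_file(path) -> tuple[NodeCloud, Optional[FiberField]]:
    """Read the node table written by :func:`write_node_file`."""
    data = np.atleast_2d(np.loadtxt(path))
    pos = data[:, 1:4]
    # drop trailing all-zero axes so 1D/2D clouds round-trip
    dim = 3
    while dim > 1 and np.allclose(pos[:, dim - 1], 0.0):
        dim -= 1
    cloud = NodeCloud(pos[:, :dim])
    fibers = None
    if data.shape[1] >= 7:
        fibers = FiberField(vectors=data[:, 4:7])
    return cloud, fibers
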