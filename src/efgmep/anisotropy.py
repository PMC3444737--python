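"""Anisotropic diffusion tensors from fiber orientation.

Conduction in myocardium is fastest along the local myocyte (fiber) direction.
In the fiber frame the diffusion tensor is diagonal,
D_local = diag(sigma_f, sigma_cf, sigma_cf); in the global frame it is
D = T D_local T^{-1}, with T = R_xz(beta) R_xy(alpha) a rotation about the
z- then y-axis aligning the first axis with the fiber. Since rotations are
orthogonal, T^{-1} = T^T and D stays symmetric with eigenvalues
{sigma_f, sigma_cf, sigma_cf}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from efgmep.errors import InvalidArgumentError
from efgmep.geometry import FiberField, NodeCloud
from efgmep.mls import ShapeEval

log = logging.getLogger(__name__)

__all__ = [
    "DiffusionParams",
    "local_tensor",
    "rotation_matrix",
    "rotate_tensor",
    "fiber_angles",
    "fiber_to_tensor",
    "tensor_field",
]


@dataclass
class DiffusionParams:
    """Conductivities along (sigma_f) and across (sigma_cf) the fiber.

    Units are whatever the active model requires: mS/mm conductivity for the
    cubic cable model, mm^2/ms diffusivity for the FitzHugh-Nagumo model.
    """

    sigma_f: float
    sigma_cf: float

    def __post_init__(self):
        if self.sigma_f <= 0 or self.sigma_cf <= 0:
            raise InvalidArgumentError("conductivities must be > 0")

    @property
    def isotropic(self) -> bool:
        return self.sigma_f == self.sigma_cf


def local_tensor(params: DiffusionParams, dim: int) -> np.ndarray:
    """Fiber-frame tensor: diag(sigma_f, sigma_cf, ..., sigma_cf)."""
    if dim not in (1, 2, 3):
        raise InvalidArgumentError("dim must be 1, 2 or 3")
    d = np.full(dim, params.sigma_cf)
    d[0] = params.sigma_f
    return np.diag(d)


def rotation_matrix(alpha: float, beta: float) -> np.ndarray:
    """T = R_xz(beta) R_xy(alpha): rotation about z by alpha then y by beta."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    r_xy = np.array([[ca, sa, 0.0], [-sa, ca, 0.0], [0.0, 0.0, 1.0]])
    r_xz = np.array([[cb, 0.0, sb], [0.0, 1.0, 0.0], [-sb, 0.0, cb]])
    return r_xz @ r_xy


def rotate_tensor(local: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Global tensor D = T D_local T^T (T orthogonal, so T^{-1} = T^T)."""
    local = np.asarray(local, dtype=float)
    if local.shape == (3, 3):
        t = rotation_matrix(alpha, beta)
    elif local.shape == (2, 2):
        t = rotation_matrix(alpha, 0.0)[:2, :2]
    elif local.shape == (1, 1):
        return local.copy()
    else:
        raise InvalidArgumentError(f"unsupported tensor shape {local.shape}")
    return t @ local @ t.T


def fiber_angles(fiber) -> tuple[float, float]:
    """(alpha, beta) such that rotation_matrix(alpha, beta) @ e1 = fiber.

    T e1 = (cos a cos b, -sin a, -cos a sin b). For fibers parallel to the
    y-axis (cos a = 0) beta is arbitrary and returned as 0.
    """
    f = np.asarray(fiber, dtype=float).ravel()
    if f.shape != (3,) or abs(np.linalg.norm(f) - 1.0) > 1e-9:
        raise InvalidArgumentError("fiber must be a unit 3-vector")
    alpha = float(np.arcsin(np.clip(-f[1], -1.0, 1.0)))
    if abs(np.cos(alpha)) < 1e-12:
        return alpha, 0.0
    beta = float(np.arctan2(-f[2], f[0]))
    return alpha, beta


def fiber_to_tensor(params: DiffusionParams, fiber) -> np.ndarray:
    """3D diffusion tensor whose sigma_f eigenvector is the given unit fiber."""
    alpha, beta = fiber_angles(fiber)
    return rotate_tensor(local_tensor(params, 3), alpha, beta)


def tensor_field(
    fibers: FiberField,
    params: DiffusionParams,
    shape_eval: ShapeEval,
    cloud: NodeCloud | None = None,
) -> np.ndarray:
    """Diffusion tensor at a quadrature point from MLS-interpolated fibers.

    The nodal fiber vectors are interpolated with the shape functions and
    renormalized. If opposing fibers cancel (interpolated norm < 1e-6), the
    fiber of the nearest contributing node is used instead (logged).
    """
    dim = shape_eval.point.shape[0]
    if fibers is None or fibers.isotropic:
        return params.sigma_cf * np.eye(dim)
    if params.isotropic:
        return params.sigma_cf * np.eye(dim)
    nodal = fibers.vectors[shape_eval.node_indices]
    f = shape_eval.phi @ nodal
    nrm = np.linalg.norm(f)
    if nrm < 1e-6:
        if cloud is None:
            raise InvalidArgumentError(
                "fiber interpolation cancelled and no cloud given for fallback"
            )
        d = np.linalg.norm(
            cloud.positions[shape_eval.node_indices] - shape_eval.point, axis=1
        )
        f = nodal[np.argmin(d)]
        log.warning(
            "fiber interpolation cancelled at %s; using nearest node's fiber",
            shape_eval.point,
        )
    else:
        f = f / nrm
    if dim == 3:
        return fiber_to_tensor(params, f)
    if dim == 2:
        alpha = float(np.arctan2(-f[1], f[0]))
        return rotate_tensor(local_tensor(params, 2), alpha, 0.0)
    return local_tensor(params, 1)
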