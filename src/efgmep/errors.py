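"""Exception hierarchy shared across the package."""


class EfgmError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(EfgmError, ValueError):
    """A caller-supplied argument violates a documented precondition."""


class DegenerateGeometryError(EfgmError):
    """Node cloud is geometrically degenerate (e.g. coincident nodes)."""


class CapacityError(EfgmError):
    """A stochastic generator could not place the requested number of nodes.

    Attributes
    ----------
    placed : int
        Number of nodes successfully placed before giving up.
    """

    def __init__(self, message: str, placed: int = 0):
        super().__init__(message)
        self.placed = placed


class SingularMomentMatrixError(EfgmError):
    """The MLS moment matrix A could not be inverted at an evaluation point."""

    def __init__(self, message: str, point=None, n_neighbors: int = 0):
        super().__init__(message)
        self.point = point
        self.n_neighbors = n_neighbors


class EmptyDomainError(EfgmError):
    """No quadrature point fell inside the problem domain."""


class BlowUpError(EfgmError):
    """The explicit time integration produced a non-finite state."""

    def __init__(self, message: str, step: int = -1, max_abs: float = float("nan")):
        super().__init__(message)
        self.step = step
        self.max_abs = max_abs


class StiffnessError(EfgmError):
    """Adaptive step control underflowed the minimum step size."""


class InsufficientDataError(EfgmError):
    """Too few usable nodes for the requested measurement."""
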