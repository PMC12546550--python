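"""Finite-difference operators on a uniform 1-D grid with no-flux boundaries.

The spatial discretization lives on ``M + 1`` equidistant nodes
``x_j = j*dx`` covering ``[0, L_f]``.  Two banded operators are provided:

* a discrete gradient ``D_x`` — central differences in the interior,
  second-order one-sided stencils at the two boundary rows;
* a discrete Laplacian ``D_xx`` — the standard three-point stencil, with
  boundary rows ``(-2, 2)/dx^2`` and ``(2, -2)/dx^2`` that encode the
  ghost-node reflection ``u_{-1} = u_1`` implied by homogeneous Neumann
  (zero normal derivative) conditions.

Both operators annihilate constants row by row, and the Neumann Laplacian
conserves the trapezoidal-weighted mass of any grid function.  The full
eigensystem of ``D_xx`` is known in closed form (discrete cosine modes),
which is exposed by :func:`laplacian_spectrum` and used by the explicit
time-step stability bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Grid1D",
    "OperatorSet",
    "build_gradient_matrix",
    "build_laplacian_matrix",
    "laplacian_spectrum",
    "build_operator_set",
    "apply_gradient",
    "apply_laplacian",
    "trapezoid_weights",
]


@dataclass(frozen=True)
class Grid1D:
    """Uniform grid on ``[0, L_f]`` with ``M`` intervals (``M + 1`` nodes).

    Parameters
    ----------
    L_f
        Domain length (dimensionless).
    M
        Number of grid intervals.  Must be at least 4 so the one-sided
        boundary stencils do not collide with each other.
    """

    L_f: float
    M: int

    def __post_init__(self) -> None:
        if self.L_f <= 0:
            raise ValueError(f"domain length must be positive, got L_f={self.L_f}")
        if self.M < 4:
            raise ValueError(
                f"need at least 4 intervals (boundary stencils span 3 nodes), got M={self.M}"
            )

    @property
    def dx(self) -> float:
        return self.L_f / self.M

    @property
    def n_nodes(self) -> int:
        return self.M + 1

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(0.0, self.L_f, self.M + 1)


def build_gradient_matrix(grid: Grid1D) -> sp.csr_matrix:
    """Discrete gradient ``D_x`` of shape ``(M+1, M+1)``.

    Interior rows carry the central stencil ``(-1, 0, 1)/(2 dx)``; row 0
    carries ``(-3, 4, -1)/(2 dx)`` and row M ``(1, -4, 3)/(2 dx)``, the
    second-order one-sided stencils.  Every row sums to zero.
    """
    M, dx = grid.M, grid.dx
    n = M + 1
    D = sp.lil_matrix((n, n))
    for j in range(1, M):
        D[j, j - 1] = -1.0
        D[j, j + 1] = 1.0
    D[0, 0], D[0, 1], D[0, 2] = -3.0, 4.0, -1.0
    D[M, M - 2], D[M, M - 1], D[M, M] = 1.0, -4.0, 3.0
    return (D / (2.0 * dx)).tocsr()


def build_laplacian_matrix(grid: Grid1D) -> sp.csr_matrix:
    """Discrete Neumann Laplacian ``D_xx`` of shape ``(M+1, M+1)``.

    Tridiagonal: interior rows ``(1, -2, 1)/dx^2``; boundary rows
    ``(-2, 2)/dx^2`` and ``(2, -2)/dx^2`` (ghost reflection ``u_{-1}=u_1``,
    ``u_{M+1}=u_{M-1}``).  Every row sums to zero.
    """
    M, dx = grid.M, grid.dx
    n = M + 1
    main = np.full(n, -2.0)
    lower = np.ones(n - 1)
    upper = np.ones(n - 1)
    upper[0] = 2.0
    lower[-1] = 2.0
    D = sp.diags([lower, main, upper], offsets=[-1, 0, 1], format="csr")
    return D / dx**2


def laplacian_spectrum(grid: Grid1D) -> np.ndarray:
    """Eigenvalues of ``D_xx`` in closed form, ordered by mode number.

    ``lambda_m = -(4/dx^2) * sin^2(m*pi*dx / (2*L_f))`` for ``m = 0..M``;
    the eigenvectors are the sampled cosines ``cos(m*pi*j/M)``.  The list
    starts at the constant mode ``lambda_0 = 0`` and decreases strictly to
    ``-4/dx^2`` at ``m = M``.
    """
    m = np.arange(grid.M + 1)
    return -(4.0 / grid.dx**2) * np.sin(m * np.pi * grid.dx / (2.0 * grid.L_f)) ** 2


@dataclass(frozen=True)
class OperatorSet:
    """Grid plus its immutable discrete gradient and Laplacian."""

    grid: Grid1D
    D_x: sp.csr_matrix = field(repr=False)
    D_xx: sp.csr_matrix = field(repr=False)


def build_operator_set(grid: Grid1D) -> OperatorSet:
    return OperatorSet(grid=grid, D_x=build_gradient_matrix(grid), D_xx=build_laplacian_matrix(grid))


def apply_gradient(u: np.ndarray, dx: float, out: np.ndarray | None = None) -> np.ndarray:
    """Apply ``D_x`` to a grid function without forming the matrix.

    Matrix-free slicing equivalent of ``build_gradient_matrix(grid) @ u``,
    used in the simulation hot path.
    """
    if out is None:
        out = np.empty_like(u)
    inv2 = 1.0 / (2.0 * dx)
    out[1:-1] = (u[2:] - u[:-2]) * inv2
    out[0] = (-3.0 * u[0] + 4.0 * u[1] - u[2]) * inv2
    out[-1] = (u[-3] - 4.0 * u[-2] + 3.0 * u[-1]) * inv2
    return out


def apply_laplacian(u: np.ndarray, dx: float, out: np.ndarray | None = None) -> np.ndarray:
    """Apply the Neumann ``D_xx`` to a grid function without forming the matrix."""
    if out is None:
        out = np.empty_like(u)
    inv = 1.0 / dx**2
    out[1:-1] = (u[2:] - 2.0 * u[1:-1] + u[:-2]) * inv
    out[0] = 2.0 * (u[1] - u[0]) * inv
    out[-1] = 2.0 * (u[-2] - u[-1]) * inv
    return out


def trapezoid_weights(grid: Grid1D) -> np.ndarray:
    """Quadrature weights ``(1/2, 1, ..., 1, 1/2) * dx``.

    Under these weights the Neumann Laplacian is exactly mass-conserving
    (the weighted sum of ``D_xx @ u`` telescopes to zero for every u).
    """
    w = np.full(grid.M + 1, grid.dx)
    w[0] *= 0.5
    w[-1] *= 0.5
    return w
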