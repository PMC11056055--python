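"""Adjacency structures and the Leroux conditional autoregressive (CAR) distribution.

Areal random effects are modelled through a Gaussian Markov random field whose
precision matrix interpolates between independence and the intrinsic CAR:

    Q(W, rho) = rho * (W_d - W) + (1 - rho) * I,

where ``W`` is a binary symmetric adjacency matrix among spatial units, ``W_d``
the diagonal matrix of its row sums (degrees), and ``rho`` in [0, 1] controls
the strength of spatial correlation.  The implied full conditional of one
effect given its neighbours is

    phi_i | phi_-i ~ N( rho * sum_j w_ij phi_j / (rho * sum_j w_ij + 1 - rho),
                        k2 / (rho * sum_j w_ij + 1 - rho) ),

with k2 the conditional variance parameter.  The same machinery applies to a
tridiagonal temporal adjacency linking consecutive time points, which is how
temporal random walks of the "CAR on the time line" type are expressed.

All joint-density computations use a single symmetric eigendecomposition of
the graph Laplacian ``W_d - W``: since Q(W, rho) shares its eigenvectors for
every rho, log-determinants and quadratic forms are O(N) after the one-off
O(N^3) factorisation, which matters inside MCMC loops.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np


class GraphValidationError(ValueError):
    """Raised when an adjacency matrix violates the structural contract."""


@dataclass(eq=False)
class SpatialGraph:
    """Binary symmetric adjacency among ``N`` spatial units.

    Parameters
    ----------
    W
        Square (N, N) matrix with entries in {0, 1}, symmetric, zero diagonal.
        Isolated units (zero row sum) are allowed.
    """

    W: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise GraphValidationError("adjacency must be a square matrix")
        if not np.array_equal(W, W.T):
            raise GraphValidationError("adjacency must be symmetric")
        if np.any(np.diag(W) != 0):
            raise GraphValidationError("adjacency diagonal must be zero")
        if not np.isin(W, (0.0, 1.0)).all():
            raise GraphValidationError("adjacency entries must be 0 or 1")
        self.W = W

    @property
    def N(self) -> int:
        return self.W.shape[0]

    @cached_property
    def degrees(self) -> np.ndarray:
        """Row sums of W (number of neighbours per unit)."""
        return self.W.sum(axis=1)

    @cached_property
    def W_d(self) -> np.ndarray:
        """Diagonal degree matrix."""
        return np.diag(self.degrees)

    @cached_property
    def laplacian(self) -> np.ndarray:
        """Graph Laplacian ``W_d - W``; positive semidefinite."""
        return self.W_d - self.W

    @cached_property
    def laplacian_eigh(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues and eigenvectors of the Laplacian (ascending)."""
        d, V = np.linalg.eigh(self.laplacian)
        # clip tiny negative round-off; Laplacian eigenvalues are >= 0
        return np.clip(d, 0.0, None), V

    @property
    def n_edges(self) -> int:
        return int(self.W.sum()) // 2


@dataclass(eq=False)
class TemporalGraph:
    """Tridiagonal 0/1 adjacency over ``T`` ordered time points.

    ``Z[i, j] = 1`` iff ``|i - j| == 1``; consecutive years are neighbours.
    """

    Z: np.ndarray

    def __post_init__(self) -> None:
        Z = np.asarray(self.Z, dtype=float)
        T = Z.shape[0]
        expected = _tridiagonal(T)
        if Z.shape != (T, T) or not np.array_equal(Z, expected):
            raise GraphValidationError(
                "temporal adjacency must be the lag-1 tridiagonal 0/1 matrix"
            )
        self.Z = Z

    @property
    def T(self) -> int:
        return self.Z.shape[0]

    # mirror the SpatialGraph surface so CAR code is structure-agnostic
    @property
    def W(self) -> np.ndarray:
        return self.Z

    @cached_property
    def degrees(self) -> np.ndarray:
        return self.Z.sum(axis=1)

    @cached_property
    def W_d(self) -> np.ndarray:
        return np.diag(self.degrees)

    @cached_property
    def laplacian(self) -> np.ndarray:
        return self.W_d - self.Z

    @cached_property
    def laplacian_eigh(self) -> tuple[np.ndarray, np.ndarray]:
        d, V = np.linalg.eigh(self.laplacian)
        return np.clip(d, 0.0, None), V


def _tridiagonal(T: int) -> np.ndarray:
    Z = np.zeros((T, T))
    idx = np.arange(T - 1)
    Z[idx, idx + 1] = 1.0
    Z[idx + 1, idx] = 1.0
    return Z


def temporal_adjacency(T: int) -> TemporalGraph:
    """Build the lag-one temporal adjacency over ``T`` time points."""
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    return TemporalGraph(_tridiagonal(int(T)))


@dataclass(frozen=True)
class CarParams:
    """Correlation strength ``rho`` in [0, 1] and conditional variance ``k2`` > 0."""

    rho: float
    k2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        if not self.k2 > 0.0:
            raise ValueError(f"k2 must be positive, got {self.k2}")


def leroux_precision(graph: SpatialGraph | TemporalGraph, rho: float) -> np.ndarray:
    """Leroux precision matrix ``rho * (W_d - W) + (1 - rho) * I``.

    Symmetric for all rho; positive definite for rho < 1 (minimum eigenvalue
    is at least ``1 - rho``).  At rho = 1 this is the singular intrinsic-CAR
    precision (the Laplacian itself).
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    N = graph.W.shape[0]
    return rho * graph.laplacian + (1.0 - rho) * np.eye(N)


def car_full_conditional(
    i: int,
    phi: np.ndarray,
    params: CarParams,
    graph: SpatialGraph | TemporalGraph,
) -> tuple[float, float]:
    """Conditional mean and variance of ``phi[i]`` given all other effects.

    Returns ``(mean, variance)`` of the Leroux CAR full conditional.  For an
    isolated unit the conditional reduces to ``N(0, k2 / (1 - rho))``.
    """
    phi = np.asarray(phi, dtype=float)
    N = graph.W.shape[0]
    if phi.shape != (N,):
        raise ValueError(f"phi must have shape ({N},), got {phi.shape}")
    if not 0 <= i < N:
        raise IndexError(f"unit index {i} out of range for N={N}")
    w_i = graph.W[i]
    denom = params.rho * w_i.sum() + 1.0 - params.rho
    mean = params.rho * float(w_i @ phi) / denom
    var = params.k2 / denom
    return mean, var


class ImproperDensityError(ValueError):
    """The joint CAR density is not defined (intrinsic limit rho = 1)."""


def car_log_density(
    phi: np.ndarray,
    params: CarParams,
    graph: SpatialGraph | TemporalGraph,
) -> float:
    """Log joint density of the Leroux CAR field at ``phi``.

    The joint distribution implied by the full conditionals is a zero-mean
    multivariate normal with precision ``Q(W, rho) / k2``; its log density is
    evaluated through the Laplacian eigendecomposition.  The intrinsic limit
    rho = 1 has a singular precision and no proper joint density: callers must
    then work with the conditionals or a constrained subspace.
    """
    if params.rho >= 1.0:
        raise ImproperDensityError(
            "rho = 1 gives the intrinsic CAR, whose joint density is improper"
        )
    phi = np.asarray(phi, dtype=float)
    N = graph.W.shape[0]
    if phi.shape != (N,):
        raise ValueError(f"phi must have shape ({N},), got {phi.shape}")
    d, V = graph.laplacian_eigh
    q = params.rho * d + (1.0 - params.rho)  # eigenvalues of Q(W, rho)
    z = V.T @ phi
    quad = float(np.sum(q * z * z))
    logdet = float(np.sum(np.log(q))) - N * np.log(params.k2)
    return 0.5 * logdet - 0.5 * N * np.log(2.0 * np.pi) - 0.5 * quad / params.k2


def morans_i(x: np.ndarray, graph: SpatialGraph) -> float:
    """Global Moran's I of ``x`` over the graph's binary weights.

    ``I = (n / S0) * sum_ij w_ij (x_i - mu)(x_j - mu) / sum_i (x_i - mu)^2``
    with ``S0`` the total weight.  Values near +1 indicate clustering of like
    values, near -1 checkerboard alternation; the statistic is not clamped and
    can exceed [-1, 1] for some weight configurations.
    """
    x = np.asarray(x, dtype=float)
    N = graph.N
    if x.shape != (N,):
        raise ValueError(f"x must have shape ({N},), got {x.shape}")
    s0 = graph.W.sum()
    if s0 == 0:
        raise ValueError("graph has no edges; Moran's I undefined (S0 = 0)")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        raise ValueError("x is constant; Moran's I undefined (zero variance)")
    return float(N / s0 * (xc @ graph.W @ xc) / denom)
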