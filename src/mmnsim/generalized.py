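"""Generalized coordinates of motion.

A smooth signal is represented by its value together with its first few
temporal derivatives (value, velocity, acceleration, ...).  This module
provides the container for such "generalized" quantities, the shift operator
``D`` that maps a generalized vector onto the generalized vector of its own
derivative, Taylor-polynomial embedding of sampled data into generalized
coordinates, and the covariance structure that smooth (analytic) noise
induces across derivative orders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import factorial


@dataclass
class GeneralizedVector:
    """A quantity and its temporal derivatives up to an embedding order.

    Parameters
    ----------
    orders : ndarray, shape (embedding_order, dim)
        Row ``k`` holds the k-th temporal derivative (row 0 is the value).
    """

    orders: np.ndarray

    def __post_init__(self) -> None:
        self.orders = np.atleast_2d(np.asarray(self.orders, dtype=float))
        if self.orders.ndim != 2:
            raise ValueError("orders must be a 2-D array (order x dim)")
        if not np.all(np.isfinite(self.orders)):
            raise ValueError("generalized vector contains non-finite entries")

    @property
    def embedding_order(self) -> int:
        return self.orders.shape[0]

    @property
    def dim(self) -> int:
        return self.orders.shape[1]

    @property
    def value(self) -> np.ndarray:
        return self.orders[0]

    def flatten(self) -> np.ndarray:
        """Order-major flat view: [value, d/dt, d2/dt2, ...]."""
        return self.orders.ravel()

    @classmethod
    def from_flat(cls, flat: np.ndarray, order: int, dim: int) -> "GeneralizedVector":
        return cls(np.asarray(flat, dtype=float).reshape(order, dim))


def shift_matrix(order: int, dim: int = 1) -> np.ndarray:
    """Block shift operator D acting on order-major flattened vectors.

    ``D @ mu.flatten()`` moves each derivative down one slot (the velocity
    block becomes the value block of the derivative, etc.); the highest
    order maps to zero.
    """
    d = np.eye(order, k=1)
    return np.kron(d, np.eye(dim))


def embedding_operator(order: int, dt: float, offsets: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares Taylor embedding of uniformly sampled data.

    Returns ``(E, offsets)`` where ``E`` has shape (order, len(offsets)) and
    ``E @ y[window]`` estimates the value and first ``order - 1`` derivatives
    at the sample with offset 0, assuming samples at ``t + offsets * dt``.
    The default window is the ``order`` samples most nearly centred on 0,
    which makes the embedding exact for polynomials of degree < order.
    """
    if order < 1:
        raise ValueError("embedding order must be >= 1")
    if offsets is None:
        offsets = np.arange(order) - (order - 1) // 2
    offsets = np.asarray(offsets, dtype=int)
    if len(offsets) < order:
        raise ValueError(f"need >= {order} samples to embed at order {order}")
    # Taylor matrix: y(t + o*dt) = sum_k (o*dt)^k / k! * y^(k)(t)
    k = np.arange(order)
    T = (offsets[:, None] * dt) ** k[None, :] / factorial(k)[None, :]
    E = np.linalg.pinv(T)
    return E, offsets


def embed(samples: np.ndarray, index: int, order: int, dt: float) -> GeneralizedVector:
    """Embed sampled data into generalized coordinates at one time point.

    Parameters
    ----------
    samples : ndarray, shape (n_times,) or (n_times, dim)
        Uniformly sampled signal.
    index : int
        Sample index at which the generalized vector is evaluated.
    order : int
        Number of orders (value + order-1 derivatives).
    dt : float
        Sample spacing.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float).T).T
    n = samples.shape[0]
    if n < order:
        raise ValueError("not enough samples for the requested embedding order")
    E, offsets = embedding_operator(order, dt)
    # clamp the window inside the array, keeping its width
    lo = offsets[0] + index
    hi = offsets[-1] + index
    shiftback = 0
    if lo < 0:
        shiftback = lo
    elif hi > n - 1:
        shiftback = hi - (n - 1)
    if shiftback != 0:
        E, _ = embedding_operator(order, dt, offsets - shiftback)
        offsets = offsets - shiftback
    window = samples[offsets + index]
    return GeneralizedVector(E @ window)


def derivative_covariance(order: int, smoothness: float) -> np.ndarray:
    """Covariance across derivative orders of a unit-variance smooth process.

    The process is stationary with Gaussian autocorrelation
    ``rho(h) = exp(-h^2 / (2 s^2))`` (``s`` = smoothness, time units).  Then
    ``Cov(x^(i), x^(j)) = (-1)^j rho^(i+j)(0)`` with
    ``rho^(2m)(0) = (-1)^m (2m-1)!! / s^(2m)``; odd totals vanish.
    """
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    V = np.zeros((order, order))
    for i in range(order):
        for j in range(order):
            if (i + j) % 2:
                continue
            m = (i + j) // 2
            rho_2m = (-1) ** m * _double_factorial(2 * m - 1) / smoothness ** (2 * m)
            V[i, j] = (-1) ** j * rho_2m
    return V


def generalized_precision(base_precision: np.ndarray, order: int, smoothness: float) -> np.ndarray:
    """Precision of a generalized random vector with smooth correlations.

    Kronecker structure: ``inv(V) (x) Pi`` where ``V`` is the derivative
    covariance of the smoothness kernel and ``Pi`` the base precision.
    """
    Pi = np.atleast_2d(np.asarray(base_precision, dtype=float))
    if Pi.shape[0] != Pi.shape[1]:
        raise ValueError("base precision must be square")
    V = derivative_covariance(order, smoothness)
    Vinv = np.linalg.inv(V)
    Pi_gen = np.kron(Vinv, Pi)
    # symmetrize against round-off; must be positive definite
    Pi_gen = 0.5 * (Pi_gen + Pi_gen.T)
    if Pi_gen.size == 0:
        return Pi_gen
    eigmin = np.linalg.eigvalsh(Pi_gen)[0]
    if eigmin <= 0:
        raise np.linalg.LinAlgError(
            f"generalized precision not positive definite (min eig {eigmin:g})"
        )
    return Pi_gen


@dataclass
class TemporalPrecision:
    """Generalized precision with its ingredients kept around for reporting."""

    base_precision: np.ndarray
    smoothness: float
    order: int
    matrix: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.base_precision = np.atleast_2d(np.asarray(self.base_precision, dtype=float))
        self.matrix = generalized_precision(self.base_precision, self.order, self.smoothness)


def _double_factorial(n: int) -> float:
    if n <= 0:
        return 1.0
    return float(np.prod(np.arange(n, 0, -2, dtype=float)))
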