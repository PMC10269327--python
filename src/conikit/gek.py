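"""Gradient-enhanced Kriging (GEK) with a Matérn-5/2 kernel.

Each data point contributes its energy and all m gradient components, so a
model over n points carries n(m+1) independent data.  The prediction is

    E*(q) = mu + v(q) . w

with a constant trend mu, a weight vector w solving M w = y (M the covariance
between the data, y the energies-minus-mu and gradients), and v the vector of
kernel values and derivatives against the data.  The kernel is

    f(d) = (1 + sqrt(5) d + 5 d^2 / 3) exp(-sqrt(5) d),
    d^2  = sum_k ((q_k - q'_k) / l_k)^2

with per-dimension characteristic lengths l_k.  The model interpolates both
energies and gradients exactly (up to the nugget used to keep the covariance
positive definite), and its predicted variance is zero at the data and grows
toward the unit prior variance far away.

Hyperparameters are fixed by construction, not by maximum likelihood: the
characteristic lengths are calibrated so that a single-point model reproduces
a supplied (approximate, diagonal) Hessian, and mu follows the caller's
baseline policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "GekDataset",
    "GekSurface",
    "GekConditioningError",
    "kernel_matern52",
    "lengths_from_hessian",
    "fit_gek",
    "predict",
]

_SQRT5 = math.sqrt(5.0)


class GekConditioningError(np.linalg.LinAlgError):
    """Covariance matrix not positive definite beyond nugget rescue."""


@dataclass
class GekDataset:
    """Training data: per point a geometry, an energy and its gradient."""

    points: list[tuple[np.ndarray, float, np.ndarray]]

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("empty dataset")
        self.points = [(np.asarray(q, dtype=float), float(v),
                        np.asarray(g, dtype=float)) for q, v, g in self.points]
        m = self.points[0][0].size
        for q, _v, g in self.points:
            if q.size != m or g.size != m:
                raise ValueError("inconsistent dimensionality in dataset")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def m(self) -> int:
        return self.points[0][0].size

    def geometries(self) -> np.ndarray:
        return np.array([q for q, _, _ in self.points])

    def min_scaled_distance(self, lengths: np.ndarray) -> float:
        """Smallest pairwise distance in kernel-scaled coordinates."""
        qs = self.geometries() / lengths
        best = math.inf
        for i in range(self.n):
            for j in range(i + 1, self.n):
                best = min(best, float(np.linalg.norm(qs[i] - qs[j])))
        return best


@dataclass
class GekSurface:
    """A fitted GEK model (weights and covariance factorization cached)."""

    dataset: GekDataset
    mu: float
    lengths: np.ndarray
    weights: np.ndarray
    nugget: float
    _cho: tuple = field(repr=False, default=None)


def _kernel_scalars(d: float) -> tuple[float, float, float]:
    """Return (f, p, e) at scaled distance d, where f is the kernel value,
    p = -f'(d)/d = (5/3)(1 + sqrt5 d) e^{-sqrt5 d} (finite at d = 0) and
    e = exp(-sqrt5 d)."""
    e = math.exp(-_SQRT5 * d)
    f = (1.0 + _SQRT5 * d + 5.0 * d * d / 3.0) * e
    p = (5.0 / 3.0) * (1.0 + _SQRT5 * d) * e
    return f, p, e


def kernel_matern52(q: np.ndarray, q_prime: np.ndarray, lengths: np.ndarray,
                    order: int = 0):
    """Matérn-5/2 kernel and its derivatives.

    order 0: f(q, q') (scalar).
    order 1: gradient with respect to q' (length-m vector).
    order 2: mixed second-derivative block d^2 f / dq dq' (m x m), i.e. the
             covariance between gradient observations at q and q'.
    """
    q = np.asarray(q, dtype=float)
    q_prime = np.asarray(q_prime, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("characteristic lengths must be positive")
    u = (q - q_prime) / lengths
    d = float(np.linalg.norm(u))
    f, p, e = _kernel_scalars(d)
    if order == 0:
        return f
    if order == 1:
        # df/dq'_k = p * u_k / l_k  (f increases as q' approaches q)
        return p * u / lengths
    if order == 2:
        block = np.diag(np.full(u.size, p)) - (25.0 / 3.0) * e * np.outer(u, u)
        return block / np.outer(lengths, lengths)
    raise ValueError("order must be 0, 1 or 2")


def lengths_from_hessian(hessian_diag: np.ndarray, mu_offset: float = 10.0,
                         min_curvature: float = 0.025) -> np.ndarray:
    """Characteristic lengths reproducing an approximate diagonal Hessian.

    A single-point GEK surface with baseline mu = y + mu_offset has Hessian
    (5/3) * mu_offset / l_k^2 on its diagonal at the data point (the kernel's
    third derivatives vanish at zero separation, so the gradient datum does
    not contribute).  Solving for l_k:

        l_k = sqrt((5/3) * mu_offset / H_kk)

    Non-positive Hessian entries are floored to ``min_curvature``
    (hartree/bohr^2) so the lengths stay positive.
    """
    h = np.maximum(np.asarray(hessian_diag, dtype=float), min_curvature)
    if mu_offset <= 0:
        raise ValueError("mu_offset must be positive")
    return np.sqrt((5.0 / 3.0) * mu_offset / h)


def _covariance_matrix(dataset: GekDataset, lengths: np.ndarray) -> np.ndarray:
    n, m = dataset.n, dataset.m
    blk = m + 1
    big = np.empty((n * blk, n * blk))
    qs = [q for q, _, _ in dataset.points]
    for i in range(n):
        for j in range(i, n):
            b = np.empty((blk, blk))
            b[0, 0] = kernel_matern52(qs[i], qs[j], lengths, order=0)
            dqp = kernel_matern52(qs[i], qs[j], lengths, order=1)
            b[0, 1:] = dqp          # cov(E_i, grad_j)
            b[1:, 0] = -dqp         # cov(grad_i, E_j) = df/dq
            b[1:, 1:] = kernel_matern52(qs[i], qs[j], lengths, order=2)
            big[i * blk:(i + 1) * blk, j * blk:(j + 1) * blk] = b
            if j > i:
                big[j * blk:(j + 1) * blk, i * blk:(i + 1) * blk] = b.T
    return big


def _data_vector(dataset: GekDataset, mu: float) -> np.ndarray:
    blk = dataset.m + 1
    y = np.empty(dataset.n * blk)
    for i, (_q, v, g) in enumerate(dataset.points):
        y[i * blk] = v - mu
        y[i * blk + 1:(i + 1) * blk] = g
    return y


def fit_gek(dataset: GekDataset, mu: float, lengths: np.ndarray,
            nugget: float = 1e-12) -> GekSurface:
    """Solve M w = y for the exact-interpolation weights.

    The covariance M gets ``nugget`` added to its diagonal for positive
    definiteness; if the Cholesky factorization still fails the nugget is
    raised twice by x100 before giving up with an error that names the
    closest pair of data points.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size != dataset.m:
        raise ValueError("lengths must match dataset dimensionality")
    dmin = dataset.min_scaled_distance(lengths)
    if dmin < 1e-10:
        raise GekConditioningError(
            f"coincident data points (min scaled distance {dmin:.3g})")
    big = _covariance_matrix(dataset, lengths)
    y = _data_vector(dataset, mu)
    eye = np.eye(big.shape[0])
    last_exc = None
    for boost in (1.0, 1e2, 1e4):
        try:
            cho = cho_factor(big + nugget * boost * eye, lower=True)
        except np.linalg.LinAlgError as exc:
            last_exc = exc
            continue
        w = cho_solve(cho, y)
        return GekSurface(dataset=dataset, mu=float(mu), lengths=lengths,
                          weights=w, nugget=nugget * boost, _cho=cho)
    qs = dataset.geometries() / lengths
    pair, best = (0, 1), math.inf
    for i in range(dataset.n):
        for j in range(i + 1, dataset.n):
            dd = float(np.linalg.norm(qs[i] - qs[j]))
            if dd < best:
                best, pair = dd, (i, j)
    raise GekConditioningError(
        f"covariance not positive definite even with boosted nugget; "
        f"closest data points are {pair[0]} and {pair[1]} "
        f"(scaled distance {best:.3g})") from last_exc


def _kernel_vector(surface: GekSurface, q: np.ndarray) -> np.ndarray:
    ds = surface.dataset
    blk = ds.m + 1
    v = np.empty(ds.n * blk)
    for j, (qj, _v, _g) in enumerate(ds.points):
        v[j * blk] = kernel_matern52(q, qj, surface.lengths, order=0)
        v[j * blk + 1:(j + 1) * blk] = kernel_matern52(
            q, qj, surface.lengths, order=1)
    return v


def predict(surface: GekSurface, q: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Predicted value, analytic gradient and variance at q.

    value    = mu + v . w
    gradient = (dv/dq) . w
    variance = f(0) - v . M^{-1} v   (unit prior variance; clipped at 0)
    """
    q = np.asarray(q, dtype=float)
    ds = surface.dataset
    blk = ds.m + 1
    v = _kernel_vector(surface, q)
    value = surface.mu + float(v @ surface.weights)

    grad = np.zeros(ds.m)
    for j, (qj, _val, _g) in enumerate(ds.points):
        w0 = surface.weights[j * blk]
        wg = surface.weights[j * blk + 1:(j + 1) * blk]
        # d/dq f(q, qj) = -df/dq' ; d/dq (df/dq'_l) = [d2f/dq dq']_{k,l}
        grad += -w0 * kernel_matern52(q, qj, surface.lengths, order=1)
        grad += kernel_matern52(q, qj, surface.lengths, order=2) @ wg

    minv_v = cho_solve(surface._cho, v)
    variance = max(0.0, 1.0 - float(v @ minv_v))
    return value, grad, variance
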