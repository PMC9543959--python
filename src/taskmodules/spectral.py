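"""The analytical link between the relevance map and motion-relevant modules.

Vectorizing each trial's standardized motion into a row of
``x in R^{K x IJ}`` and taking its thin SVD ``x = U H V^T`` gives
motion-relevant *spatiotemporal* modules ``v_r`` (rows of V^T, mixing
spatial and temporal structure) with weights ``omega_r``.  Because V is
orthonormal, the ridge solution rewrites exactly as

    w = (x^T x + sigma^2 I)^{-1} x^T d
      = V (H H^T + sigma^2 I)^{-1} V^T x^T d
      = sum_r  f(omega_r) * g_{v_r} * v_r ,

with ``f(omega_r) = 1 / (omega_r^2 + sigma^2)`` (monotonically
decreasing in omega_r) and ``g_{v_r} = beta . v_r`` where
``beta = x^T d`` is the per-feature motion-performance coupling.  The
relevance map is therefore the motion-relevant spectrum re-weighted by
how strongly each spectral module covaries with performance -- a
module's rank in reconstructing the motion does not determine its task
relevance.

Note on scaling: with the package's population (1/K) standardization,
``beta_i = sum_k x_{k,i} d_k`` equals K times the Pearson correlation
Cor(x_i, d).  The identity above holds with the un-divided beta; both
``beta`` and ``beta / K`` (the correlation) are stored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpectralBasis",
    "SpectralWeights",
    "vectorized_svd",
    "relevance_via_spectrum",
    "spectral_weights",
]


@dataclass
class SpectralBasis:
    """Thin SVD of the trial-vectorized motion ``x = U H V^T``.

    ``omega`` (R,) non-increasing singular values, ``U`` (K, R) trial-side
    factors, ``V`` (R, IJ) with spatiotemporal modules v_r as rows.
    Numerically-zero singular values are dropped, so R is the numerical
    rank of x.
    """

    omega: np.ndarray
    U: np.ndarray
    V: np.ndarray
    n_features: int

    @property
    def rank(self) -> int:
        return self.omega.size

    def reconstruct(self) -> np.ndarray:
        return (self.U * self.omega) @ self.V

    def beta(self, d: np.ndarray) -> np.ndarray:
        """``x^T d`` computed from the factors: sum_r omega_r (u_r . d) v_r."""
        d = np.asarray(d, dtype=float).ravel()
        return (self.omega * (self.U.T @ d)) @ self.V


@dataclass
class SpectralWeights:
    """The Eq-style weights of the spectral construction of the ridge map.

    ``f[r] = 1/(omega_r^2 + sigma^2)``, ``g[r] = beta . v_r``; the map is
    ``w = sum_r f[r] g[r] v_r``.  ``beta`` is x^T d; ``beta_over_K`` is
    the per-feature Pearson correlation Cor(x_i, d) under population
    standardization.
    """

    f: np.ndarray
    g: np.ndarray
    beta: np.ndarray
    beta_over_K: np.ndarray
    sigma2: float


def vectorized_svd(x: np.ndarray) -> SpectralBasis:
    """Thin SVD of the (K, IJ) trial-vectorized motion.

    Uses the same deterministic sign convention as the task-relevant
    decomposition (largest-magnitude element of each v_r positive).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("motion matrix contains non-finite values")
    U, omega, Vt = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (omega[0] if omega.size else 0.0)
    R = int(np.sum(omega > tol))
    U, omega, Vt = U[:, :R], omega[:R], Vt[:R]
    for r in range(R):
        peak = np.argmax(np.abs(Vt[r]))
        if Vt[r, peak] < 0:
            Vt[r] = -Vt[r]
            U[:, r] = -U[:, r]
    return SpectralBasis(omega=omega, U=U, V=Vt, n_features=x.shape[1])


def relevance_via_spectrum(
    basis: SpectralBasis, d: np.ndarray, sigma2: float
) -> np.ndarray:
    """Construct the ridge relevance map from the motion spectrum.

    Returns ``w = sum_r v_r (v_r . x^T d) / (omega_r^2 + sigma^2)``.
    For sigma^2 > 0 the ridge solution lies in the row space of x, so
    the null-space term is identically zero and the restriction to the
    thin SVD is exact.  At sigma^2 = 0 the construction requires x to
    have full column rank.
    """
    d = np.asarray(d, dtype=float).ravel()
    if d.size != basis.U.shape[0]:
        raise ValueError(f"d has {d.size} trials, basis has {basis.U.shape[0]}")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if sigma2 == 0.0 and basis.rank < basis.n_features:
        raise ValueError(
            "sigma2 = 0 with rank-deficient motion: the inverse does not exist"
        )
    coef = basis.omega * (basis.U.T @ d) / (basis.omega**2 + sigma2)
    return coef @ basis.V


def spectral_weights(
    basis: SpectralBasis, d: np.ndarray, sigma2: float
) -> SpectralWeights:
    """Per-module weights f(omega_r) and g_{v_r} of the spectral construction.

    ``sum_r f[r] g[r] v_r`` reproduces :func:`relevance_via_spectrum`
    exactly.
    """
    d = np.asarray(d, dtype=float).ravel()
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if sigma2 == 0.0 and basis.rank < basis.n_features:
        raise ValueError(
            "sigma2 = 0 with rank-deficient motion: the inverse does not exist"
        )
    beta = basis.beta(d)
    f = 1.0 / (basis.omega**2 + sigma2)
    g = basis.V @ beta
    K = basis.U.shape[0]
    return SpectralWeights(f=f, g=g, beta=beta, beta_over_K=beta / K, sigma2=sigma2)
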