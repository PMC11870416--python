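"""Sample covariance structure and the Gaussian likelihood of locations.

The tip locations of the sample paths are modelled as
``Lp ~ N(R μ, σ² Sp)`` — independent Brownian displacements down every edge,
roots fixed at μ.  Conditioning all paths that end at the same sample to end
at the same location turns the path matrix into the sample matrix
``S = (Pᵀ Sp⁻ P)⁻¹``, the covariance structure of the observed sample
locations.  In two dimensions the dispersal rate is a 2×2 matrix Σ and the
covariance factorizes as a Kronecker product (Σ across dimensions, Sp across
paths), which is how the density is evaluated here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelSpec",
    "generalized_inverse",
    "sample_matrix",
    "add_root_variance",
    "log_likelihood",
]


@dataclass
class ModelSpec:
    """Parameters of the Brownian dispersal model.

    ``mu`` is the nr × d matrix of root locations; ``sigma2`` the scalar
    dispersal rate (d = 1) or the 2×2 dispersal matrix Σ (d = 2);
    ``root_variance`` optionally relaxes the zero-variance-root assumption
    (scalar shared across roots, or one value per root)."""

    mu: np.ndarray
    sigma2: np.ndarray | float
    root_variance: float | np.ndarray | None = None

    def __post_init__(self):
        self.mu = np.atleast_2d(np.asarray(self.mu, float))
        s = np.atleast_2d(np.asarray(self.sigma2, float))
        if s.shape == (1, 1):
            if s[0, 0] <= 0:
                raise ValueError("sigma2 must be positive")
        else:
            if np.any(np.linalg.eigvalsh(0.5 * (s + s.T)) <= 0):
                raise ValueError("Sigma must be positive definite")
        if self.root_variance is not None and np.any(
            np.asarray(self.root_variance) < 0
        ):
            raise ValueError("root_variance must be non-negative")

    @property
    def ndim(self) -> int:
        s = np.atleast_2d(np.asarray(self.sigma2, float))
        return 2 if s.shape == (2, 2) else 1

_LOG2PI = float(np.log(2.0 * np.pi))


def _check_symmetric(M, tol=1e-8, name="matrix"):
    M = np.asarray(M, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    scale = max(np.abs(M).max(), 1.0)
    if np.abs(M - M.T).max() > tol * scale:
        raise ValueError(f"{name} is not symmetric")
    return 0.5 * (M + M.T)


def generalized_inverse(M: np.ndarray, rtol: float | None = None) -> np.ndarray:
    """Moore–Penrose pseudoinverse of a symmetric PSD matrix.

    Eigenvalues below ``rtol ×`` the largest are treated as zero; default
    rtol is 1e-10 × dimension.
    """
    M = _check_symmetric(M)
    if rtol is None:
        rtol = 1e-10 * M.shape[0]
    w, U = np.linalg.eigh(M)
    cut = rtol * max(np.abs(w).max(), np.finfo(float).tiny)
    inv = np.where(np.abs(w) > cut, 1.0 / np.where(np.abs(w) > cut, w, 1.0), 0.0)
    return (U * inv) @ U.T


def _eig_support(M, rtol=None):
    M = _check_symmetric(M)
    if rtol is None:
        rtol = 1e-10 * M.shape[0]
    w, U = np.linalg.eigh(M)
    cut = rtol * max(np.abs(w).max(), np.finfo(float).tiny)
    keep = w > cut
    return w[keep], U[:, keep]


def sample_matrix(Sp: np.ndarray, P: np.ndarray, rtol: float | None = None) -> np.ndarray:
    """Sample matrix ``S = (Pᵀ Sp⁻ P)⁻¹``: the covariance structure of sample
    locations after conditioning coincident-sample paths to coincide."""
    Spg = generalized_inverse(Sp, rtol)
    inner = P.T @ Spg @ P
    try:
        S = np.linalg.inv(inner)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "Pᵀ Sp⁻ P is singular; the sample-location covariance is "
            "degenerate — work in path space with the path likelihood instead"
        ) from err
    return 0.5 * (S + S.T)


def add_root_variance(Sp: np.ndarray, R: np.ndarray, v) -> np.ndarray:
    """Relax the zero-variance-root assumption: add variance ``v`` to the
    covariance of every pair of paths sharing a root (``Sp + R diag(v) Rᵀ``;
    scalar v is shared across roots)."""
    v = np.asarray(v, float)
    if np.any(v < 0):
        raise ValueError("root variance must be non-negative")
    if v.ndim == 0:
        v = np.full(R.shape[1], float(v))
    return Sp + (R * v) @ R.T


def log_likelihood(
    Sp: np.ndarray,
    P: np.ndarray,
    R: np.ndarray,
    locations: np.ndarray,
    mu: np.ndarray,
    sigma2,
    rtol: float | None = None,
    support_tol: float = 1e-6,
) -> float:
    """Log-density of the path-tip locations ``P ℓ*`` under ``N(R μ, σ² Sp)``.

    Handles singular Sp via the pseudo-determinant restricted to its support;
    if the residual has a component off the support larger than
    ``support_tol`` (relative), the constraint is violated and −inf is
    returned.  ``sigma2`` is a positive scalar (d = 1) or a 2×2 dispersal
    matrix Σ (d = 2).
    """
    loc = np.atleast_2d(np.asarray(locations, float))
    if loc.shape[0] == 1 and P.shape[1] != 1:
        loc = loc.T
    mu = np.atleast_2d(np.asarray(mu, float))
    if mu.shape[0] == 1 and R.shape[1] != 1:
        mu = mu.T
    d = loc.shape[1]
    X = P @ loc - R @ mu  # np × d residual
    w, U = _eig_support(Sp, rtol)
    r = len(w)
    if r == 0:
        return -np.inf
    Z = U.T @ X  # support coordinates
    off = X - U @ Z
    scale = max(np.abs(X).max(), 1.0)
    if np.abs(off).max() > support_tol * scale:
        return -np.inf
    logpdet = float(np.sum(np.log(w)))
    Q = (Z.T / w) @ Z  # d × d matrix of quadratic forms Xᵀ Sp⁻ X
    if d == 1:
        s2 = float(np.asarray(sigma2).reshape(()))
        if s2 <= 0:
            raise ValueError("sigma2 must be positive")
        return -0.5 * (r * (_LOG2PI + np.log(s2)) + logpdet + Q[0, 0] / s2)
    Sigma = _check_symmetric(np.asarray(sigma2, float), name="Sigma")
    sign, logdet_sigma = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise ValueError("Sigma must be positive definite")
    quad = float(np.trace(np.linalg.solve(Sigma, Q)))
    return -0.5 * (
        d * r * _LOG2PI + r * logdet_sigma + d * logpdet + quad
    )
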