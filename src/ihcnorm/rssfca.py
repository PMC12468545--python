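"""Robust Self-Sparse Fuzzy Clustering (RSSFCA) for pixel segmentation.

Fuzzy clustering under a Gaussian (Mahalanobis) dissimilarity with a
quadratic membership regularizer:

    J = sum_ij u_ij * Phi'(x_j | v_i, Sigma_i) + gamma * sum_ij u_ij^2,

subject to column-stochastic memberships (0 <= u_ij <= 1, sum_i u_ij = 1).
Phi(x|v,Sigma) = -ln rho(x|v,Sigma) is the Gaussian negative
log-likelihood; when covariances shrink, Phi can go negative, so Phi' is
Phi shifted up by its (global) minimum whenever that minimum is negative.
Unlike the classic fuzzy c-means exponent, the quadratic regularizer makes
the optimal memberships *exactly sparse*: the per-pixel subproblem is a
Euclidean projection onto the probability simplex, which zeroes out
clusters whose dissimilarity is too large.

Alternating updates: memberships by the simplex-projection closed form,
centers by membership-weighted means, covariances by membership-weighted
scatter plus a small diagonal ridge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure


@dataclass
class RssfcaParams:
    """c: clusters; gamma: membership regularizer (on the feature scale in
    use — defaults assume [0, 1]-scaled RGB); eta: convergence threshold on
    the objective; max_iter: iteration cap; cov_ridge: diagonal loading
    keeping covariances positive-definite."""

    c: int = 2
    gamma: float = 3.0
    eta: float = 1e-5
    max_iter: int = 100
    seed: int = 0
    cov_ridge: float = 1e-6

    def __post_init__(self):
        if self.c < 2:
            raise ValueError("need at least 2 clusters")
        if self.gamma <= 0 or self.eta <= 0 or self.cov_ridge <= 0:
            raise ValueError("gamma, eta and cov_ridge must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class FuzzyState:
    U: np.ndarray                     # c x n memberships, columns sum to 1
    centers: np.ndarray               # c x D
    covariances: np.ndarray           # c x D x D
    objective: float
    n_iter: int = 0
    converged: bool = False
    objective_history: list[float] = field(default_factory=list)


def gaussian_neglog(x: np.ndarray, center: np.ndarray,
                    covariance: np.ndarray) -> float:
    """Negative log of the multivariate Gaussian density at ``x``."""
    x = np.asarray(x, float)
    v = np.asarray(center, float)
    cov = np.asarray(covariance, float)
    d = x.shape[-1]
    chol = np.linalg.cholesky(cov)
    z = np.linalg.solve(chol, (x - v))
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return float(0.5 * (z @ z) + 0.5 * d * np.log(2.0 * np.pi) + 0.5 * logdet)


def _neglog_matrix(X: np.ndarray, centers: np.ndarray,
                   covariances: np.ndarray) -> np.ndarray:
    """Phi as a c x n matrix for n x D data."""
    n, d = X.shape
    c = centers.shape[0]
    Phi = np.empty((c, n))
    const = 0.5 * d * np.log(2.0 * np.pi)
    for i in range(c):
        chol = np.linalg.cholesky(covariances[i])
        z = np.linalg.solve(chol, (X - centers[i]).T)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        Phi[i] = 0.5 * np.einsum("ij,ij->j", z, z) + const + 0.5 * logdet
    return Phi


def shift_phi(Phi: np.ndarray) -> np.ndarray:
    """Shift the dissimilarity matrix to be non-negative.

    If the global minimum is negative, subtract it from every entry;
    otherwise return Phi unchanged. A uniform shift leaves every per-column
    argmin (and, with column-stochastic memberships, the minimizer of the
    membership subproblem) unchanged.
    """
    Phi = np.asarray(Phi, float)
    m = Phi.min()
    return Phi - m if m < 0 else Phi


def update_memberships(PhiPrime: np.ndarray, gamma: float) -> np.ndarray:
    """Closed-form membership update.

    Per pixel j, minimize sum_i (u_i * Phi'_ij + gamma * u_i^2) over the
    simplex. Completing the square, this is the Euclidean projection of
    -Phi'_j / (2 gamma) onto the probability simplex, computed by the
    standard O(c log c) sort-and-threshold rule; memberships hit exact
    zeros for clusters with large dissimilarity (self-sparsity).
    """
    PhiPrime = np.asarray(PhiPrime, float)
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    Z = -PhiPrime / (2.0 * gamma)                    # c x n
    c = Z.shape[0]
    Zs = -np.sort(-Z, axis=0)                        # descending per column
    css = np.cumsum(Zs, axis=0)
    k = np.arange(1, c + 1)[:, None]
    cond = Zs - (css - 1.0) / k > 0
    rho = cond.sum(axis=0)                           # support size per column
    theta = (css[rho - 1, np.arange(Z.shape[1])] - 1.0) / rho
    return np.maximum(Z - theta, 0.0)


def update_centers(U: np.ndarray, X: np.ndarray,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Membership-weighted means; an empty cluster is reseeded from a random
    data point."""
    U = np.asarray(U, float)
    X = np.asarray(X, float)
    mass = U.sum(axis=1)
    centers = np.empty((U.shape[0], X.shape[1]))
    for i in range(U.shape[0]):
        if mass[i] <= 1e-12:
            if rng is None:
                rng = np.random.default_rng(0)
            centers[i] = X[rng.integers(X.shape[0])]
        else:
            centers[i] = (U[i] @ X) / mass[i]
    return centers


def update_covariances(U: np.ndarray, X: np.ndarray, centers: np.ndarray,
                       cov_ridge: float = 1e-6) -> np.ndarray:
    """Membership-weighted scatter matrices plus a diagonal ridge."""
    U = np.asarray(U, float)
    X = np.asarray(X, float)
    c, d = centers.shape
    covs = np.empty((c, d, d))
    eye = np.eye(d)
    for i in range(c):
        w = U[i]
        mass = w.sum()
        if mass <= 1e-12:
            covs[i] = eye * max(cov_ridge, 1e-6)
            continue
        diff = X - centers[i]
        covs[i] = (diff.T * w) @ diff / mass + cov_ridge * eye
    return covs


def _objective(U, PhiPrime, gamma):
    return float(np.sum(U * PhiPrime) + gamma * np.sum(U * U))


def _fcm_init(X: np.ndarray, c: int, rng: np.random.Generator,
              n_iter: int = 20, m: float = 2.0):
    """Standard fuzzy c-means (fuzzifier m) used only for initialization."""
    n = X.shape[0]
    centers = X[rng.choice(n, size=c, replace=False)].astype(float)
    U = np.full((c, n), 1.0 / c)
    for _ in range(n_iter):
        d2 = np.maximum(
            ((X[None, :, :] - centers[:, None, :]) ** 2).sum(axis=2), 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0))
        U = inv / inv.sum(axis=0, keepdims=True)
        Um = U ** m
        centers = (Um @ X) / Um.sum(axis=1, keepdims=True)
    return U, centers


def rssfca_fit(X: np.ndarray, params: RssfcaParams | None = None) -> FuzzyState:
    """Fit the self-sparse fuzzy clustering model to n x D data.

    Memberships and centers are initialized with plain fuzzy c-means,
    covariances from the weighted scatter of that initialization; the
    alternating updates then run until the objective changes by at most
    ``eta`` or ``max_iter`` is hit.
    """
    if params is None:
        params = RssfcaParams()
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] <= params.c:
        raise ValueError("need n > c data points of dimension D")
    rng = np.random.default_rng(params.seed)
    U, centers = _fcm_init(X, params.c, rng)
    covs = update_covariances(U, X, centers, params.cov_ridge)

    history = []
    converged = False
    t = 0
    for t in range(1, params.max_iter + 1):
        PhiP = shift_phi(_neglog_matrix(X, centers, covs))
        U = update_memberships(PhiP, params.gamma)
        centers = update_centers(U, X, rng)
        covs = update_covariances(U, X, centers, params.cov_ridge)
        PhiP = shift_phi(_neglog_matrix(X, centers, covs))
        history.append(_objective(U, PhiP, params.gamma))
        if len(history) > 1 and abs(history[-1] - history[-2]) <= params.eta:
            converged = True
            break
    return FuzzyState(U, centers, covs, history[-1], t, converged, history)


_LUMA = np.array([0.299, 0.587, 0.114])


def segment_image(image: np.ndarray, params: RssfcaParams | None = None,
                  min_area_fraction: float = 1e-4) -> np.ndarray:
    """Segment an RGB image into background (0) and nuclei (1).

    Pixels are clustered on [0, 1]-scaled RGB features; the cluster whose
    center has the highest luminance is called background and everything
    else nuclei. Connected nuclei components smaller than
    ``min_area_fraction`` of the image are returned to background (a simple
    area filter standing in for more elaborate over-segmentation control).
    """
    image = np.asarray(image, float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    if params is None:
        params = RssfcaParams()
    h, w = image.shape[:2]
    X = image.reshape(-1, 3) / 255.0
    if np.allclose(X, X[0]):          # constant image: all background
        return np.zeros((h, w), dtype=np.uint8)
    state = rssfca_fit(X, params)
    labels = state.U.argmax(axis=0)
    background = int(np.argmax(state.centers @ _LUMA))
    mask = (labels != background).reshape(h, w)
    if mask.any() and min_area_fraction > 0:
        comp = measure.label(mask, connectivity=2)
        min_area = min_area_fraction * h * w
        for region in measure.regionprops(comp):
            if region.area < min_area:
                mask[comp == region.label] = False
    return mask.astype(np.uint8)
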