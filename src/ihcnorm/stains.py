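"""Stain separation: estimating stain color vectors and per-pixel densities.

An IHC image in optical-density space factorizes as ``OD = V @ S`` where the
columns of V (3 x r) are unit-norm stain color vectors and the rows of
S (r x n) are non-negative per-pixel stain densities. Three estimators are
provided:

* :func:`macenko_stain_vectors` — the SVD/angle-percentile method: project
  filtered OD tuples onto their dominant plane and take robust extreme
  angular directions as the stain vectors;
* :func:`nmf_factorize` — plain non-negative matrix factorization,
  min (1/2)||OD - VS||_F^2 with V, S >= 0;
* :func:`snmf_factorize` — sparse NMF, the same objective plus an l1
  penalty lambda * sum_j ||S(j,:)||_1 under unit-norm columns of V. With
  lambda = 0 this reduces exactly to plain NMF.

The sparse coder (:func:`sparse_code`) solves the per-pixel non-negative
LASSO by coordinate descent, vectorized over all pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import StainEstimationError

# Canonical OD-space stain directions (standard brightfield deconvolution
# values), used only to give the two estimated columns a deterministic
# hematoxylin-first / DAB-second ordering.
CANONICAL_HEMATOXYLIN = np.array([0.650, 0.704, 0.286])
CANONICAL_HEMATOXYLIN = CANONICAL_HEMATOXYLIN / np.linalg.norm(CANONICAL_HEMATOXYLIN)
CANONICAL_DAB = np.array([0.269, 0.568, 0.778])
CANONICAL_DAB = CANONICAL_DAB / np.linalg.norm(CANONICAL_DAB)

DEFAULT_STAIN_NAMES = ("hematoxylin", "dab")


@dataclass
class StainBasis:
    """Unit-norm stain color vectors: columns of the 3 x r matrix V."""

    V: np.ndarray
    names: tuple[str, ...] = DEFAULT_STAIN_NAMES

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=np.float64)
        if self.V.ndim != 2 or self.V.shape[0] != 3:
            raise ValueError("stain basis must be a 3 x r matrix")
        if self.V.shape[1] not in (1, 2, 3):
            raise ValueError("only 1 to 3 stains are supported")
        if np.any(self.V < -1e-12):
            raise ValueError("stain vectors must be non-negative")
        norms = np.linalg.norm(self.V, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("stain vectors must have unit Euclidean norm")

    @property
    def r(self) -> int:
        return self.V.shape[1]


@dataclass
class MacenkoParams:
    """Parameters for the SVD/angle-percentile stain estimator.

    beta
        OD threshold: pixels whose maximum-channel OD is below beta are
        dropped before the SVD (they are mostly background and carry no
        stain direction information). ``None`` disables the filter.
    alpha
        Robust-extreme percentile: stain vectors are read off at the
        alpha-th and (100 - alpha)-th percentiles of the angle distribution.
    """

    beta: float | None = 0.15
    alpha: float = 1.0

    def __post_init__(self):
        if self.beta is not None and self.beta < 0:
            raise ValueError("beta must be >= 0 (or None to disable filtering)")
        if not (0 < self.alpha < 50):
            raise ValueError("alpha must lie in (0, 50)")


@dataclass
class SNMFParams:
    """Parameters for the (sparse) NMF solver."""

    lambda_sparsity: float = 0.1
    max_iters: int = 200
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.lambda_sparsity < 0:
            raise ValueError("lambda_sparsity must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


@dataclass
class FactorizationResult:
    basis: StainBasis
    density: np.ndarray          # r x n
    objective: float
    n_iter: int
    converged: bool
    objective_history: list[float] = field(default_factory=list)


def _check_od_matrix(od: np.ndarray) -> np.ndarray:
    od = np.asarray(od, dtype=np.float64)
    if od.ndim != 2 or od.shape[0] != 3:
        raise ValueError("expected a 3 x n OD matrix")
    if not np.all(np.isfinite(od)):
        raise ValueError("OD matrix contains non-finite values")
    if od.min(initial=0.0) < 0:
        raise ValueError("OD matrix must be non-negative")
    return od


def macenko_stain_vectors(od: np.ndarray,
                          params: MacenkoParams | None = None) -> StainBasis:
    """Estimate the two stain vectors by SVD and robust angle extremes.

    Steps: drop low-OD pixels (max-channel OD < beta); compute the rank-2
    singular subspace of the remaining OD tuples; project onto that plane
    and normalize; take the directions at the alpha / (100 - alpha)
    percentiles of the in-plane angle; map back to OD space, clip tiny
    negative components, renormalize, and order hematoxylin-first.

    Raises
    ------
    StainEstimationError
        If fewer than 3 pixels survive the filter or the OD cloud is
        effectively rank-1 (a single stain carries no second direction).
    """
    if params is None:
        params = MacenkoParams()
    od = _check_od_matrix(od)
    if params.beta is not None:
        od = od[:, od.max(axis=0) >= params.beta]
    if od.shape[1] < 3:
        raise StainEstimationError("fewer than 3 pixels survive the OD filter")

    u, s, _ = np.linalg.svd(od, full_matrices=False)
    if s[0] <= 0 or s[1] / s[0] < 1e-6:
        raise StainEstimationError("OD cloud is rank-deficient (single stain?)")
    basis2 = u[:, :2]
    # Deterministic sign: flip each direction so the mean projection is >= 0.
    proj = basis2.T @ od                       # 2 x n
    for k in range(2):
        if proj[k].mean() < 0:
            basis2[:, k] = -basis2[:, k]
            proj[k] = -proj[k]
    norms = np.linalg.norm(proj, axis=0)
    keep = norms > 1e-12
    if keep.sum() < 3:
        raise StainEstimationError("too few pixels with measurable stain")
    phi = np.arctan2(proj[1, keep], proj[0, keep])
    lo, hi = np.percentile(phi, [params.alpha, 100.0 - params.alpha])
    vecs = []
    for ang in (lo, hi):
        v = basis2 @ np.array([np.cos(ang), np.sin(ang)])
        v = np.clip(v, 0.0, None)
        nrm = np.linalg.norm(v)
        if nrm < 1e-12:
            raise StainEstimationError("extreme direction collapsed to zero")
        vecs.append(v / nrm)
    return order_stains(StainBasis(np.column_stack(vecs)))


def stain_order(V: np.ndarray) -> np.ndarray:
    """Permutation putting the hematoxylin-like column first, DAB-like second.

    Each column is assigned to the canonical direction it subtends the
    smaller angle with. If both columns are closer to the same canonical
    direction, fall back to ordering by blue-channel OD weight (hematoxylin
    absorbs little blue light, DAB much), with a warning.
    """
    V = np.asarray(V, dtype=np.float64)
    r = V.shape[1]
    if r == 2:
        cos_h = V.T @ CANONICAL_HEMATOXYLIN
        cos_d = V.T @ CANONICAL_DAB
        pref = cos_h > cos_d                   # True -> looks like hematoxylin
        if pref[0] and not pref[1]:
            return np.array([0, 1])
        if pref[1] and not pref[0]:
            return np.array([1, 0])
        warnings.warn("ambiguous stain assignment; ordering by blue OD weight",
                      stacklevel=2)
        return np.argsort(V[2, :])
    # r == 3: order the two most canonical-like columns, residual last.
    cos_h = V.T @ CANONICAL_HEMATOXYLIN
    cos_d = V.T @ CANONICAL_DAB
    ih = int(np.argmax(cos_h))
    id_ = int(np.argmax(np.where(np.arange(r) == ih, -np.inf, cos_d)))
    rest = [k for k in range(r) if k not in (ih, id_)]
    return np.array([ih, id_] + rest)


def order_stains(basis: StainBasis) -> StainBasis:
    """Return the basis with columns in canonical (negative, positive) order."""
    perm = stain_order(basis.V)
    names = DEFAULT_STAIN_NAMES if basis.r == 2 else ("hematoxylin", "dab", "residual")
    return StainBasis(basis.V[:, perm], names)


def sparse_code(od: np.ndarray, basis: StainBasis | np.ndarray,
                lambda_sparsity: float = 0.1,
                max_iters: int = 500, tol: float = 1e-12) -> np.ndarray:
    """Non-negative LASSO coding of each pixel against a fixed stain basis.

    Solves, independently per pixel j,

        min_{s >= 0}  (1/2) ||od_j - V s||^2  +  lambda * ||s||_1

    by cyclic coordinate descent, vectorized across pixels. The problem is
    convex and strictly convex in each coordinate (unit-norm columns), so
    the iteration converges to the unique per-coordinate fixed point.
    """
    V = basis.V if isinstance(basis, StainBasis) else np.asarray(basis, dtype=np.float64)
    od = _check_od_matrix(od)
    if lambda_sparsity < 0:
        raise ValueError("lambda_sparsity must be >= 0")
    r, n = V.shape[1], od.shape[1]
    G = V.T @ V                                 # r x r Gram matrix
    C = V.T @ od                                # r x n correlations
    S = np.zeros((r, n))
    for _ in range(max_iters):
        delta = 0.0
        for k in range(r):
            resid = C[k] - G[k] @ S + G[k, k] * S[k]
            new = np.maximum(0.0, (resid - lambda_sparsity) / G[k, k])
            delta = max(delta, float(np.abs(new - S[k]).max(initial=0.0)))
            S[k] = new
        if delta <= tol:
            break
    return S


def _objective(od, V, S, lam):
    resid = od - V @ S
    return 0.5 * float(np.sum(resid * resid)) + lam * float(np.abs(S).sum())


def _init_dictionary(od: np.ndarray, r: int, rng: np.random.Generator) -> np.ndarray:
    """Warm-start V from the SVD/angle estimator when possible, else from
    random data pixels."""
    if r == 2:
        try:
            return macenko_stain_vectors(od, MacenkoParams()).V.copy()
        except StainEstimationError:
            pass
    norms = np.linalg.norm(od, axis=0)
    candidates = np.flatnonzero(norms > 1e-8)
    if candidates.size >= r:
        idx = rng.choice(candidates, size=r, replace=False)
        V = od[:, idx] / norms[idx]
    else:
        V = np.abs(rng.standard_normal((3, r)))
        V /= np.linalg.norm(V, axis=0)
    return V


def snmf_factorize(od: np.ndarray, r: int = 2,
                   params: SNMFParams | None = None) -> FactorizationResult:
    """Sparse NMF by alternating sparse coding and dictionary updates.

    S-step: :func:`sparse_code` (exact per-pixel non-negative LASSO).
    V-step: block coordinate descent over columns with projection onto the
    non-negative unit ball, followed by a rescaling to exactly unit column
    norm with the compensating inverse scaling of the S rows (which leaves
    V @ S unchanged and can only decrease the l1 penalty). The penalized
    objective is therefore non-increasing across outer iterations.
    """
    if params is None:
        params = SNMFParams()
    od = _check_od_matrix(od)
    if r < 1:
        raise ValueError("r must be >= 1")
    lam = params.lambda_sparsity
    rng = np.random.default_rng(params.seed)
    V = _init_dictionary(od, r, rng)
    S = sparse_code(od, V, lam)
    history = [_objective(od, V, S, lam)]
    converged = False
    it = 0
    for it in range(1, params.max_iters + 1):
        # Dictionary update (V-step).
        SSt = S @ S.T
        odSt = od @ S.T
        for j in range(r):
            if SSt[j, j] <= 1e-14:
                # Dead stain: restart its column from a random data pixel.
                warnings.warn(f"stain column {j} lost all support; reinitializing",
                              stacklevel=2)
                norms = np.linalg.norm(od, axis=0)
                cand = np.flatnonzero(norms > 1e-8)
                if cand.size:
                    k = int(rng.choice(cand))
                    V[:, j] = od[:, k] / norms[k]
                continue
            u = V[:, j] + (odSt[:, j] - V @ SSt[:, j]) / SSt[j, j]
            u = np.clip(u, 0.0, None)
            nrm = np.linalg.norm(u)
            if nrm <= 1e-12:
                continue
            if nrm > 1.0:
                u /= nrm           # projection onto the unit ball
                nrm = 1.0
            # Rescale to exactly unit norm; compensate in S (VS unchanged,
            # l1 penalty scaled down by nrm <= 1).
            V[:, j] = u / nrm
            S[j] *= nrm
        # Sparse coding (S-step).
        S = sparse_code(od, V, lam)
        f = _objective(od, V, S, lam)
        history.append(f)
        if abs(history[-2] - f) <= params.tol * max(1.0, abs(history[-2])):
            converged = True
            break
    names = DEFAULT_STAIN_NAMES if r == 2 else tuple(f"stain{k}" for k in range(r))
    basis = StainBasis(np.clip(V, 0.0, None) / np.linalg.norm(V, axis=0), names)
    return FactorizationResult(basis, S, history[-1], it, converged, history)


def nmf_factorize(od: np.ndarray, r: int = 2,
                  params: SNMFParams | None = None) -> FactorizationResult:
    """Plain NMF: min (1/2)||OD - VS||_F^2 with V, S >= 0.

    Implemented as SNMF with the sparsity weight forced to zero (the two
    objectives coincide at lambda = 0).
    """
    if params is None:
        params = SNMFParams()
    return snmf_factorize(od, r, replace(params, lambda_sparsity=0.0))


def lambda_grid_search(od: np.ndarray, r: int, lambdas, params: SNMFParams | None = None):
    """Pick the sparsity weight minimizing reconstruction error over a grid.

    Returns ``(best_lambda, {lambda: reconstruction_error})``. Off by
    default everywhere; provided as the tuning helper for users who want a
    data-driven lambda.
    """
    if params is None:
        params = SNMFParams()
    od = _check_od_matrix(od)
    errors = {}
    for lam in lambdas:
        res = snmf_factorize(od, r, replace(params, lambda_sparsity=float(lam)))
        resid = od - res.basis.V @ res.density
        errors[float(lam)] = float(np.linalg.norm(resid) / max(np.linalg.norm(od), 1e-12))
    best = min(errors, key=errors.get)
    return best, errors
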