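"""Structure-Preserving Color Normalization (SPCN).

The color appearance of a source image is mapped onto that of a
pathologist-preferred target while leaving the source's stain *structure*
(the spatial density maps) untouched: both images are factorized into
stain basis x density in OD space, each source density row is rescaled so
its robust pseudo-maximum (a high quantile, default the 99% level) matches
the target's, and the rescaled source densities are recombined with the
*target's* stain basis:

    S_s_norm(j,:) = S_s(j,:) * RM(S_t)(j) / RM(S_s)(j)
    OD_s_norm     = V_t @ S_s_norm

Because each row is only multiplied by a positive scalar, the support and
relative spatial pattern of every stain are preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .exceptions import DegenerateStainError
from .od import image_to_od_matrix, od_matrix_to_image
from .stains import SNMFParams, snmf_factorize, sparse_code, stain_order


@dataclass
class PseudoMax:
    """Per-stain robust row maxima of a density matrix."""

    rm: np.ndarray
    quantile: float = 0.99


def row_pseudo_max(S: np.ndarray, quantile: float = 0.99) -> PseudoMax:
    """Empirical per-row quantile (linear interpolation between order
    statistics) of a non-negative density matrix."""
    S = np.asarray(S, dtype=np.float64)
    if S.ndim != 2 or S.shape[1] < 1:
        raise ValueError("density matrix must be r x n with n >= 1")
    if not (0 < quantile <= 1):
        raise ValueError("quantile must lie in (0, 1]")
    return PseudoMax(np.quantile(S, quantile, axis=1), quantile)


def normalize_density(Ss: np.ndarray, rm_source: PseudoMax,
                      rm_target: PseudoMax) -> np.ndarray:
    """Rescale each source density row to the target pseudo-maximum."""
    Ss = np.asarray(Ss, dtype=np.float64)
    rs, rt = np.asarray(rm_source.rm, float), np.asarray(rm_target.rm, float)
    if Ss.shape[0] != rs.shape[0] or rs.shape != rt.shape:
        raise ValueError("stain count mismatch between densities and pseudo-maxima")
    out = Ss.copy()
    for j in range(Ss.shape[0]):
        if rs[j] <= 0:
            if np.any(Ss[j] > 0):
                raise DegenerateStainError(
                    f"stain row {j} has zero pseudo-maximum but nonzero density")
            warnings.warn(f"stain row {j} is empty; passed through unscaled",
                          stacklevel=2)
            continue
        out[j] = Ss[j] * (rt[j] / rs[j])
    return out


def spcn_normalize(source: np.ndarray, target: np.ndarray,
                   snmf_params: SNMFParams | None = None,
                   quantile: float = 0.99,
                   reconstruction_lambda: float = 0.0,
                   return_artifacts: bool = False):
    """Normalize ``source`` toward ``target``; both are H x W x 3 RGB images.

    Each image is factorized with sparse NMF and its stains put in canonical
    (hematoxylin, DAB) order so rows correspond across images. The density
    matrices used for the quantile matching and the reconstruction are
    re-coded against the fitted bases with ``reconstruction_lambda`` (default
    0, i.e. non-negative least squares): the l1 weight is a fitting device
    for the basis, and carrying its shrinkage into the reconstruction would
    bias the output brighter than the source.
    """
    if snmf_params is None:
        snmf_params = SNMFParams()
    od_s = image_to_od_matrix(source)
    od_t = image_to_od_matrix(target)
    res_s = snmf_factorize(od_s, 2, snmf_params)
    res_t = snmf_factorize(od_t, 2, snmf_params)
    perm_s = stain_order(res_s.basis.V)
    perm_t = stain_order(res_t.basis.V)
    Vs = res_s.basis.V[:, perm_s]
    Vt = res_t.basis.V[:, perm_t]
    Ss = sparse_code(od_s, Vs, reconstruction_lambda)
    St = sparse_code(od_t, Vt, reconstruction_lambda)
    rm_s = row_pseudo_max(Ss, quantile)
    rm_t = row_pseudo_max(St, quantile)
    Ss_norm = normalize_density(Ss, rm_s, rm_t)
    od_norm = Vt @ Ss_norm
    out = od_matrix_to_image(od_norm, source.shape[:2])
    if return_artifacts:
        return out, {
            "V_source": Vs, "V_target": Vt,
            "S_source": Ss, "S_target": St, "S_source_norm": Ss_norm,
            "rm_source": rm_s, "rm_target": rm_t,
        }
    return out
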