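"""Quaternion Structural Similarity (QSSIM) for color images.

Each RGB pixel (r, g, b) on the [0, 1] scale is treated as a pure
quaternion q = r*i + g*j + b*k, so luminance and chrominance degrade a
single vectorial quantity instead of three independent scalars. Over each
sliding window the score multiplies

* a luminance term  2 |mu_ref| |mu_deg| / (|mu_ref|^2 + |mu_deg|^2), where
  mu is the quaternion (vector) mean — the quaternion modulus is
  multiplicative, so |mu_ref * conj(mu_deg)| factorizes; and
* a structural term 2 |sigma_rd| / (sigma_ref^2 + sigma_deg^2), where
  sigma_rd is the quaternion cross-covariance mean[(q_r - mu_r) *
  conj(q_d - mu_d)] (Hamilton product; for pure quaternions a * conj(b) =
  a.b - a x b, a full quaternion whose modulus cancels only under genuine
  structural/chromatic decorrelation), and sigma^2 the mean squared
  modulus of the centered quaternions.

Both terms are stabilized with a small epsilon added to numerator and
denominator, which fixes the 0/0 constant-window limit at 1 and keeps the
score within [0, 1] (Cauchy–Schwarz bounds |sigma_rd| <= sigma_r sigma_d).
The image score is the mean over all windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class QssimParams:
    window: int = 8
    stride: int = 1
    epsilon: float = 1e-12

    def __post_init__(self):
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def to_quaternion(image: np.ndarray) -> np.ndarray:
    """Map an 8-bit-scale RGB image to its pure-quaternion components
    (H x W x 3 float array of the i, j, k parts; the scalar part is 0)."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    return image / 255.0


def from_quaternion(q: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_quaternion` (exact on the stored components)."""
    return np.asarray(q, dtype=np.float64) * 255.0


def _box_means(a: np.ndarray, w: int, stride: int) -> np.ndarray:
    """Means of all w x w windows (valid positions, given stride) via an
    integral image."""
    ii = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
    ii[1:, 1:] = a.cumsum(axis=0).cumsum(axis=1)
    s = (ii[w:, w:] - ii[:-w, w:] - ii[w:, :-w] + ii[:-w, :-w])
    return s[::stride, ::stride] / (w * w)


def qssim_score(ref: np.ndarray, deg: np.ndarray,
                params: QssimParams | None = None,
                global_window: bool = False) -> float:
    """QSSIM between a reference and a degraded image; higher is better,
    1 means identical.

    With ``global_window`` the statistics are pooled once over the whole
    image instead of over sliding windows.
    """
    if params is None:
        params = QssimParams()
    qr = to_quaternion(ref)
    qd = to_quaternion(deg)
    if qr.shape != qd.shape:
        raise ValueError("reference and degraded images must have equal shape")
    h, w3 = qr.shape[:2]
    win = min(h, w3) if global_window else params.window
    if win > min(h, w3):
        raise ValueError("window larger than image")
    stride = 1 if global_window else params.stride
    eps = params.epsilon

    mu_r = [_box_means(qr[..., c], win, stride) for c in range(3)]
    mu_d = [_box_means(qd[..., c], win, stride) for c in range(3)]
    e_rr = [_box_means(qr[..., c] ** 2, win, stride) for c in range(3)]
    e_dd = [_box_means(qd[..., c] ** 2, win, stride) for c in range(3)]
    e_rd = [[_box_means(qr[..., a] * qd[..., b], win, stride)
             for b in range(3)] for a in range(3)]

    mod2_mu_r = sum(m * m for m in mu_r)
    mod2_mu_d = sum(m * m for m in mu_d)
    var_r = np.clip(sum(e_rr) - mod2_mu_r, 0.0, None)
    var_d = np.clip(sum(e_dd) - mod2_mu_d, 0.0, None)

    def cov(a, b):
        return e_rd[a][b] - mu_r[a] * mu_d[b]

    # Hamilton product of centered pure quaternions a * conj(b):
    # scalar part = a.b, vector part = -(a x b), window-averaged.
    s0 = cov(0, 0) + cov(1, 1) + cov(2, 2)
    s1 = -(cov(1, 2) - cov(2, 1))
    s2 = -(cov(2, 0) - cov(0, 2))
    s3 = -(cov(0, 1) - cov(1, 0))
    mod_sigma_rd = np.sqrt(s0 * s0 + s1 * s1 + s2 * s2 + s3 * s3)

    lum = (2.0 * np.sqrt(mod2_mu_r * mod2_mu_d) + eps) / (mod2_mu_r + mod2_mu_d + eps)
    struct = (2.0 * mod_sigma_rd + eps) / (var_r + var_d + eps)
    score = float(np.mean(lum * struct))
    return min(max(score, 0.0), 1.0)
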