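"""Beer–Lambert conversions between RGB intensity space and optical density (OD).

Transmitted light through a stained specimen follows the Beer–Lambert law
``I = I0 * exp(-A*c)``: stain concentration is linear in optical density
``OD = -log(I / I0)`` but non-linear in raw RGB values, so all stain
separation and normalization arithmetic in this package happens in OD space.
"""

from __future__ import annotations

import numpy as np

#: Intensity floor applied before the log. A zero-intensity pixel has
#: infinite nominal OD; flooring at 1 bounds OD at log(255) ~ 5.54, the
#: dynamic range of an 8-bit sensor.
OD_FLOOR = 1.0

#: Default illuminant ("blank") intensity for 8-bit images.
DEFAULT_BLANK = 255.0


def rgb_to_od(image: np.ndarray, blank: float | np.ndarray = DEFAULT_BLANK) -> np.ndarray:
    """Forward Beer–Lambert transform: intensities -> optical densities.

    Parameters
    ----------
    image
        Array of intensities on the 8-bit scale [0, 255]. Any shape; if
        ``blank`` is per-channel it must broadcast against the last axis.
    blank
        Illuminant intensity per channel (scalar or length-3), > 0.

    Returns
    -------
    Non-negative float64 array of optical densities, same shape as ``image``.
    """
    image = np.asarray(image, dtype=np.float64)
    blank = np.asarray(blank, dtype=np.float64)
    if np.any(blank <= 0):
        raise ValueError("blank illuminant intensity must be positive")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if image.min(initial=0.0) < 0 or image.max(initial=0.0) > 255:
        raise ValueError("image intensities must lie in [0, 255]")
    clamped = np.clip(image, OD_FLOOR, blank)
    return -np.log(clamped / blank)


def od_to_rgb(od: np.ndarray, blank: float | np.ndarray = DEFAULT_BLANK) -> np.ndarray:
    """Inverse Beer–Lambert transform: optical densities -> intensities.

    Output is ``blank * exp(-od)`` clipped to [0, 255] (float; callers decide
    when to quantize to uint8).
    """
    od = np.asarray(od, dtype=np.float64)
    blank = np.asarray(blank, dtype=np.float64)
    if np.any(blank <= 0):
        raise ValueError("blank illuminant intensity must be positive")
    if np.any(od < 0):
        raise ValueError("optical densities must be non-negative")
    return np.clip(blank * np.exp(-od), 0.0, 255.0)


def image_to_od_matrix(image: np.ndarray, blank: float | np.ndarray = DEFAULT_BLANK) -> np.ndarray:
    """Flatten an H x W x 3 image into the 3 x n OD matrix used by factorizations."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    od = rgb_to_od(image, blank)
    return od.reshape(-1, 3).T


def od_matrix_to_image(od_matrix: np.ndarray, shape: tuple[int, int],
                       blank: float | np.ndarray = DEFAULT_BLANK) -> np.ndarray:
    """Invert :func:`image_to_od_matrix`: 3 x n OD matrix -> H x W x 3 intensities."""
    od_matrix = np.asarray(od_matrix, dtype=np.float64)
    h, w = shape
    if od_matrix.shape != (3, h * w):
        raise ValueError(f"OD matrix shape {od_matrix.shape} does not match image shape {shape}")
    od = od_matrix.T.reshape(h, w, 3)
    return od_to_rgb(np.clip(od, 0.0, None), blank)
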