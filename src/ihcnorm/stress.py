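"""STRESS: Spatio-Temporal Retinex-like Envelope with Stochastic Sampling.

A Retinex-flavored local contrast stretch. For every pixel p0, random
"sprays" of M samples are drawn from a disk of radius R around it; over N
iterations the sample range r_i = s_max - s_min and the relative position
v_i = (p0 - s_min) / r_i of the center pixel are averaged into r-bar and
v-bar, which define per-pixel min/max envelopes

    E_min = p0 - v_bar * r_bar,     E_max = E_min + r_bar,

and the stretched value p = (p0 - E_min) / (E_max - E_min). Each color
channel is processed independently on the [0, 1] scale.

Conventions (the published description leaves these open):

* spray samples are uniform over the disk *area*, drawn by inverse
  transform (radius = R * sqrt(u)); samples falling outside the image are
  redrawn a bounded number of times, then clamped to the border;
* the center pixel is excluded from the spray and repeats are allowed;
* v_i is clipped to [0, 1], which guarantees E_min <= p0 <= E_max even
  when a spray misses the local extrema;
* a constant neighborhood (r_bar = 0) maps to 0.5, extending the
  v_i = 1/2 zero-range convention of the per-spray rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

_MAX_REDRAWS = 8


@dataclass
class StressParams:
    """Sampling parameters for STRESS.

    radius
        Spray disk radius R in pixels. ``None`` means max(H, W): every spray
        can reach the whole image, which reads global illumination.
    samples
        Samples per spray (M).
    iterations
        Number of sprays averaged per pixel (N).
    seed
        Master RNG seed; per-channel streams are derived from it.
    """

    radius: int | None = None
    samples: int = 30
    iterations: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.radius is not None and self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.samples < 1 or self.iterations < 1:
            raise ValueError("samples and iterations must be >= 1")


def _draw_offsets(n: int, m: int, radius: float, rng: np.random.Generator):
    """Uniform-over-disk-area integer offsets, shape (n, m) each for rows/cols."""
    u = rng.random((n, m))
    theta = rng.random((n, m)) * (2.0 * np.pi)
    rad = radius * np.sqrt(u)
    return np.rint(rad * np.sin(theta)).astype(np.int64), \
        np.rint(rad * np.cos(theta)).astype(np.int64)


def _spray_coords(rows0, cols0, radius, shape, rng):
    """Spray coordinates for many centers at once.

    rows0, cols0: (n, m) arrays of center coordinates (already broadcast).
    Returns (rows, cols) inside the image, center excluded where possible.
    """
    h, w = shape
    n, m = rows0.shape
    dr, dc = _draw_offsets(n, m, radius, rng)
    rows, cols = rows0 + dr, cols0 + dc
    for _ in range(_MAX_REDRAWS):
        bad = (rows < 0) | (rows >= h) | (cols < 0) | (cols >= w) | \
              ((rows == rows0) & (cols == cols0))
        k = int(bad.sum())
        if k == 0:
            break
        u = rng.random(k)
        theta = rng.random(k) * (2.0 * np.pi)
        rad = radius * np.sqrt(u)
        rows[bad] = rows0[bad] + np.rint(rad * np.sin(theta)).astype(np.int64)
        cols[bad] = cols0[bad] + np.rint(rad * np.cos(theta)).astype(np.int64)
    np.clip(rows, 0, h - 1, out=rows)
    np.clip(cols, 0, w - 1, out=cols)
    return rows, cols


def sample_spray(center: tuple[int, int], params: StressParams,
                 image_extent: tuple[int, int],
                 rng: np.random.Generator) -> list[tuple[int, int]]:
    """Draw one spray of M pixel coordinates around ``center`` (row, col).

    Samples are uniform over the disk of radius R, lie inside the image, and
    exclude the center itself. A degenerate 1 x 1 image yields an empty spray.
    """
    h, w = image_extent
    r0, c0 = center
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError("spray center outside image")
    if h * w <= 1:
        return []
    radius = params.radius if params.radius is not None else max(h, w)
    rows0 = np.full((1, params.samples), r0, dtype=np.int64)
    cols0 = np.full((1, params.samples), c0, dtype=np.int64)
    rows, cols = _spray_coords(rows0, cols0, radius, (h, w), rng)
    return list(zip(rows.ravel().tolist(), cols.ravel().tolist()))


@njit(cache=True)
def _stress_kernel(flat, h, w, radius, m, n_iter, rng):  # pragma: no cover
    """Per-pixel spray loop (compiled). Same sampling law as
    :func:`_spray_coords`: uniform over the disk area, out-of-image (or
    center) hits redrawn up to the retry budget, then clamped."""
    n = h * w
    out = np.empty(n)
    r2 = radius * radius
    # Budget of raw draws per sample; square-rejection accepts pi/4 of them.
    budget = 2 * (_MAX_REDRAWS + 1)
    for p in range(n):
        r0 = p // w
        c0 = p % w
        p0 = flat[p]
        acc_r = 0.0
        acc_v = 0.0
        for _ in range(n_iter):
            smax = -1.0e300
            smin = 1.0e300
            for _s in range(m):
                rr = r0
                cc = c0
                for _t in range(budget):
                    # Uniform over the disk area by rejection from the
                    # bounding square (identical law to polar r*sqrt(u)).
                    dy = radius * (2.0 * rng.random() - 1.0)
                    dx = radius * (2.0 * rng.random() - 1.0)
                    if dy * dy + dx * dx > r2:
                        continue
                    rr = r0 + int(np.rint(dy))
                    cc = c0 + int(np.rint(dx))
                    if 0 <= rr < h and 0 <= cc < w and not (rr == r0 and cc == c0):
                        break
                if rr < 0:
                    rr = 0
                elif rr >= h:
                    rr = h - 1
                if cc < 0:
                    cc = 0
                elif cc >= w:
                    cc = w - 1
                v = flat[rr * w + cc]
                if v > smax:
                    smax = v
                if v < smin:
                    smin = v
            ri = smax - smin
            if ri > 0.0:
                vi = (p0 - smin) / ri
                if vi < 0.0:
                    vi = 0.0
                elif vi > 1.0:
                    vi = 1.0
            else:
                vi = 0.5
            acc_r += ri
            acc_v += vi
        # (p0 - Emin) / (Emax - Emin) with Emin = p0 - vbar*rbar and
        # Emax - Emin = rbar reduces to vbar; the rbar = 0 limit is 0.5.
        out[p] = acc_v / n_iter if acc_r > 0.0 else 0.5
    return out


def stress_channel(channel: np.ndarray, params: StressParams,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply STRESS to one scalar plane; returns values in [0, 1]."""
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2:
        raise ValueError("expected a 2-D scalar plane")
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite values")
    h, w = channel.shape
    if h * w == 1:
        return np.full_like(channel, 0.5)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    radius = float(params.radius if params.radius is not None else max(h, w))
    out = _stress_kernel(channel.ravel(), h, w, radius,
                         params.samples, params.iterations, rng)
    return np.clip(out, 0.0, 1.0).reshape(h, w)


def stress_image(image: np.ndarray, params: StressParams) -> np.ndarray:
    """Apply STRESS to each channel of an 8-bit-scale RGB image.

    The image is scaled to [0, 1], each channel is processed with its own
    RNG stream derived from ``params.seed``, and the result is rescaled to
    [0, 255] (float64).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    streams = np.random.SeedSequence(params.seed).spawn(3)
    out = np.empty_like(image)
    for c in range(3):
        rng = np.random.default_rng(streams[c])
        out[..., c] = stress_channel(image[..., c] / 255.0, params, rng=rng) * 255.0
    return out
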