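"""Synthetic two-stain IHC scene generator with full ground truth.

Emulates the appearance that the rest of the package operates on — a white
background with non-overlapping disk-shaped nuclei, each carrying either a
hematoxylin-like (blue, immunonegative) or DAB-like (brown, immunopositive)
stain — while exposing everything real images hide: the exact stain basis,
the per-pixel density matrix, the nuclei mask and the per-nucleus labels.
Scenes are rendered through the same Beer–Lambert forward model the
analysis inverts: OD = V @ S (+ Gaussian OD noise), image = IBLT(OD).

Each nucleus has a smooth cosine radial density profile (peak at the
center, a visible fraction of the peak at the rim); the background is
unstained (pure white) by
default, with an optional uniform haze density on both stains. No chromatin
texture, nucleus overlap or scanner noise model is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cnacd import NEGATIVE, POSITIVE, NucleusAnnotation
from .exceptions import ConfigError
from .od import od_to_rgb
from .stains import CANONICAL_DAB, CANONICAL_HEMATOXYLIN, StainBasis


@dataclass
class SynthConfig:
    """Scene parameters.

    Densities are OD-scale stain amounts: each nucleus's dominant stain
    peaks at a value drawn from ``density_range`` and falls off with a
    cosine radial profile to ``rim_fraction`` of the peak at the rim (real
    nuclei have a visible boundary, not a fade to nothing);
    ``cross_density`` is the peak of the opposite stain inside a nucleus
    (0 = pure single-stain nuclei); ``background_density`` is a uniform
    haze on both stains; ``noise_sigma`` is the standard deviation of
    additive Gaussian noise in OD space.
    """

    height: int = 256
    width: int = 256
    n_nuclei: int = 12
    radius_range: tuple[int, int] = (8, 16)
    fraction_positive: float = 0.5
    density_range: tuple[float, float] = (0.8, 1.2)
    rim_fraction: float = 0.3
    cross_density: float = 0.0
    background_density: float = 0.0
    noise_sigma: float = 0.01
    basis: StainBasis | None = None
    seed: int = 0
    max_place_tries: int = 2000

    def __post_init__(self):
        if self.height < 8 or self.width < 8:
            raise ConfigError("scene must be at least 8 x 8")
        if self.n_nuclei < 0:
            raise ConfigError("n_nuclei must be >= 0")
        if not (0 <= self.fraction_positive <= 1):
            raise ConfigError("fraction_positive must lie in [0, 1]")
        if self.radius_range[0] < 2 or self.radius_range[1] < self.radius_range[0]:
            raise ConfigError("invalid radius_range")
        if min(self.density_range) < 0 or self.cross_density < 0 \
                or self.background_density < 0 or self.noise_sigma < 0:
            raise ConfigError("densities and noise must be non-negative")
        if not (0 <= self.rim_fraction <= 1):
            raise ConfigError("rim_fraction must lie in [0, 1]")


def default_basis() -> StainBasis:
    """The canonical hematoxylin/DAB OD basis used when none is supplied."""
    return StainBasis(np.column_stack([CANONICAL_HEMATOXYLIN, CANONICAL_DAB]))


@dataclass
class SyntheticScene:
    image: np.ndarray                 # H x W x 3 uint8
    nuclei_mask: np.ndarray           # H x W bool
    nucleus_labels: list[tuple[tuple[int, int], int, str]]  # ((x, y), radius, label)
    true_basis: StainBasis
    true_density: np.ndarray          # 2 x n, noise-free
    noise_sigma: float
    seed: int
    config: SynthConfig = field(repr=False, default=None)


def _place_disks(cfg: SynthConfig, rng: np.random.Generator):
    """Rejection-sample non-overlapping disk centers and radii."""
    placed = []  # (row, col, radius)
    tries = 0
    while len(placed) < cfg.n_nuclei:
        tries += 1
        if tries > cfg.max_place_tries:
            raise ConfigError(
                f"could not place {cfg.n_nuclei} non-overlapping nuclei "
                f"in {cfg.height} x {cfg.width} after {cfg.max_place_tries} tries")
        radius = int(rng.integers(cfg.radius_range[0], cfg.radius_range[1] + 1))
        row = int(rng.integers(radius + 1, cfg.height - radius - 1))
        col = int(rng.integers(radius + 1, cfg.width - radius - 1))
        if all((row - r0) ** 2 + (col - c0) ** 2 > (radius + r1 + 1) ** 2
               for r0, c0, r1 in placed):
            placed.append((row, col, radius))
    return placed


def make_scene(config: SynthConfig | None = None) -> SyntheticScene:
    """Render a synthetic IHC scene with known ground truth."""
    cfg = config if config is not None else SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    basis = cfg.basis if cfg.basis is not None else default_basis()
    h, w = cfg.height, cfg.width

    disks = _place_disks(cfg, rng)
    n_pos = int(round(cfg.fraction_positive * len(disks)))
    is_positive = np.zeros(len(disks), dtype=bool)
    if disks:
        is_positive[rng.permutation(len(disks))[:n_pos]] = True

    density = np.full((2, h, w), cfg.background_density)
    mask = np.zeros((h, w), dtype=bool)
    labels = []
    rows, cols = np.mgrid[0:h, 0:w]
    for (row, col, radius), pos in zip(disks, is_positive):
        dist = np.sqrt((rows - row) ** 2 + (cols - col) ** 2)
        inside = dist < radius
        falloff = 0.5 * (1.0 + np.cos(np.pi * dist[inside] / radius))
        profile = cfg.rim_fraction + (1.0 - cfg.rim_fraction) * falloff
        peak = rng.uniform(*cfg.density_range)
        primary = 1 if pos else 0            # row 0 hematoxylin, row 1 DAB
        density[primary][inside] += peak * profile
        if cfg.cross_density > 0:
            density[1 - primary][inside] += cfg.cross_density * profile
        mask |= inside
        labels.append(((col, row), radius, POSITIVE if pos else NEGATIVE))

    S = density.reshape(2, h * w)
    od = (basis.V @ S).T.reshape(h, w, 3)
    if cfg.noise_sigma > 0:
        od = np.clip(od + rng.normal(0.0, cfg.noise_sigma, od.shape), 0.0, None)
    image = np.rint(od_to_rgb(od)).astype(np.uint8)
    return SyntheticScene(image, mask, labels, basis, S, cfg.noise_sigma,
                          cfg.seed, cfg)


def scene_to_annotations(scene: SyntheticScene) -> list[NucleusAnnotation]:
    """One center-pixel annotation per nucleus, carrying the generating label."""
    if not scene.nucleus_labels:
        raise ValueError("scene has no nuclei")
    return [NucleusAnnotation(x=c[0], y=c[1], label=lab)
            for c, _radius, lab in scene.nucleus_labels]
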