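"""The end-to-end IHC color-normalization pipeline.

Stages: (1) STRESS contrast-stretch both source and target; (2–5) SPCN on
the stretched pair (Beer–Lambert to OD, sparse NMF stain separation with
canonical stain ordering, pseudo-maximum density matching, inverse
transform); (6) RSSFCA segmentation of the *stretched source* into nuclei
and background; (7) merge: nuclei pixels come from the SPCN output,
background pixels from the STRESS output — nuclei get the target's color
appearance while the background keeps its clean stretched white.

All stage seeds are derived from the single master seed by fixed offsets,
so the whole run — and each stage in isolation — is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import PipelineStageError
from .rssfca import RssfcaParams, segment_image
from .spcn import spcn_normalize
from .stains import MacenkoParams, SNMFParams
from .stress import StressParams, stress_image

# Fixed per-stage seed offsets from the master seed.
_SEED_STRESS_SOURCE = 1
_SEED_STRESS_TARGET = 2
_SEED_SNMF = 3
_SEED_RSSFCA = 4


@dataclass
class PipelineConfig:
    stress: StressParams = field(default_factory=StressParams)
    snmf: SNMFParams = field(default_factory=SNMFParams)
    macenko: MacenkoParams = field(default_factory=MacenkoParams)
    rssfca: RssfcaParams = field(default_factory=RssfcaParams)
    quantile: float = 0.99
    min_area_fraction: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.quantile <= 1):
            raise ValueError("quantile must lie in (0, 1]")
        if self.min_area_fraction < 0:
            raise ValueError("min_area_fraction must be >= 0")

    def stage_params(self):
        """Sub-parameter sets with stage seeds derived from the master seed."""
        base = int(self.seed)
        return {
            "stress_source": replace(self.stress, seed=base + _SEED_STRESS_SOURCE),
            "stress_target": replace(self.stress, seed=base + _SEED_STRESS_TARGET),
            "snmf": replace(self.snmf, seed=base + _SEED_SNMF),
            "rssfca": replace(self.rssfca, seed=base + _SEED_RSSFCA),
        }


def merge(spcn_image: np.ndarray, stress_image_: np.ndarray,
          mask: np.ndarray) -> np.ndarray:
    """Compose the final image: SPCN pixels where ``mask`` marks nuclei,
    STRESS pixels elsewhere."""
    spcn_image = np.asarray(spcn_image)
    stress_image_ = np.asarray(stress_image_)
    mask = np.asarray(mask).astype(bool)
    if spcn_image.shape != stress_image_.shape or mask.shape != spcn_image.shape[:2]:
        raise ValueError("merge inputs must share dimensions")
    return np.where(mask[..., None], spcn_image, stress_image_)


def normalize_ihc(source: np.ndarray, target: np.ndarray,
                  config: PipelineConfig | None = None,
                  return_intermediates: bool = False):
    """Run the full normalization on a source/target RGB image pair.

    Returns the normalized uint8 image, or ``(image, intermediates)`` with
    the per-stage artifacts (stretched source/target, SPCN output, nuclei
    mask) when ``return_intermediates`` is set.
    """
    if config is None:
        config = PipelineConfig()
    source = np.asarray(source)
    target = np.asarray(target)
    stages = config.stage_params()

    def run(stage, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:                       # noqa: BLE001
            raise PipelineStageError(stage, exc) from exc

    stress_src = run("stress_source", stress_image, source, stages["stress_source"])
    stress_tgt = run("stress_target", stress_image, target, stages["stress_target"])
    spcn_out = run("spcn", spcn_normalize, stress_src, stress_tgt,
                   snmf_params=stages["snmf"], quantile=config.quantile)
    mask = run("segment", segment_image, stress_src, stages["rssfca"],
               min_area_fraction=config.min_area_fraction)
    merged = run("merge", merge, spcn_out, stress_src, mask)
    out = np.rint(np.clip(merged, 0, 255)).astype(np.uint8)
    if return_intermediates:
        return out, {
            "stress_source": stress_src,
            "stress_target": stress_tgt,
            "spcn": spcn_out,
            "mask": mask,
        }
    return out
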