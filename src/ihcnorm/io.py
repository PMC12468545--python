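"""Image, annotation and configuration I/O.

PNG is the canonical (lossless) intermediate format; JPEG and TIFF are
accepted on input. Annotations travel as CSV with 0-based ``x`` (column),
``y`` (row) coordinates and a ``label`` column holding ``+`` / ``-``.
Pipeline configurations are YAML files mirroring
:class:`~ihcnorm.pipeline.PipelineConfig`; a :class:`RunManifest` records
everything needed to re-run a normalization bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .cnacd import NucleusAnnotation
from .exceptions import ConfigError, IHCNormError
from .pipeline import PipelineConfig
from .rssfca import RssfcaParams
from .stains import MacenkoParams, SNMFParams
from .stress import StressParams


def read_image(path) -> np.ndarray:
    """Read an image as H x W x 3 uint8 RGB.

    Grayscale inputs are promoted to three channels; an alpha channel is
    dropped with a warning; 16-bit data are rescaled to 8 bits with a
    warning.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise IHCNormError(f"cannot read image '{path}': {exc}") from exc
    if arr.dtype == np.uint16:
        warnings.warn(f"'{path}': 16-bit input rescaled to 8-bit", stacklevel=2)
        arr = (arr.astype(np.float64) / 257.0)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        warnings.warn(f"'{path}': alpha channel dropped", stacklevel=2)
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise IHCNormError(f"'{path}': unsupported image layout {arr.shape}")
    return np.rint(np.clip(arr.astype(np.float64), 0, 255)).astype(np.uint8)


def write_image(image: np.ndarray, path) -> None:
    """Write an RGB image (any float/int on the 8-bit scale) losslessly."""
    path = Path(path)
    arr = np.rint(np.clip(np.asarray(image, dtype=np.float64), 0, 255)).astype(np.uint8)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, arr)


def read_annotations(path) -> list[NucleusAnnotation]:
    """Read point annotations from a CSV with columns x, y[, label]."""
    df = pd.read_csv(path)
    if not {"x", "y"}.issubset(df.columns):
        raise IHCNormError(f"'{path}': annotation CSV needs 'x' and 'y' columns")
    has_label = "label" in df.columns
    return [NucleusAnnotation(int(r.x), int(r.y),
                              str(r.label) if has_label else None)
            for r in df.itertuples()]


def write_annotations(annotations, path, predictions=None) -> None:
    rows = []
    for i, a in enumerate(annotations):
        row = {"x": a.x, "y": a.y, "label": a.label}
        if predictions is not None:
            row["predicted"] = predictions[i]
        rows.append(row)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_basis_csv(V: np.ndarray, path, names=None) -> None:
    """Write a 3 x r stain basis as CSV (rows R, G, B; one column per stain)."""
    V = np.asarray(V)
    cols = list(names) if names is not None else [f"stain{j}" for j in range(V.shape[1])]
    df = pd.DataFrame(V, index=["R", "G", "B"], columns=cols)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path)


_SUBCONFIGS = {
    "stress": StressParams,
    "snmf": SNMFParams,
    "macenko": MacenkoParams,
    "rssfca": RssfcaParams,
}
_SCALARS = {"quantile", "min_area_fraction", "seed"}


def load_config(path) -> PipelineConfig:
    """Load a pipeline configuration from YAML.

    Missing keys take their defaults; unknown keys are rejected; invariant
    violations raise :class:`ConfigError` naming the offending key.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"'{path}': top level must be a mapping")
    kwargs = {}
    for key, value in raw.items():
        if key in _SUBCONFIGS:
            cls = _SUBCONFIGS[key]
            if not isinstance(value, dict):
                raise ConfigError(f"'{key}' must be a mapping")
            valid = {f.name for f in dataclasses.fields(cls)}
            unknown = set(value) - valid
            if unknown:
                raise ConfigError(f"unknown key(s) {sorted(unknown)} under '{key}'")
            try:
                kwargs[key] = cls(**value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid '{key}' configuration: {exc}") from exc
        elif key in _SCALARS:
            kwargs[key] = value
        else:
            raise ConfigError(f"unknown configuration key '{key}'")
    try:
        return PipelineConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def config_to_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def input_hash(*arrays: np.ndarray) -> str:
    """Dependency-free provenance hash of input pixel data."""
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(a)
        h.update(str(a.shape).encode())
        h.update(str(a.dtype).encode())
        h.update(a.tobytes())
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Everything needed to reproduce a pipeline run bit-identically."""

    config: dict
    seed: int
    inputs_sha256: str
    outputs: dict
    stage_flags: dict = dataclasses.field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text
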