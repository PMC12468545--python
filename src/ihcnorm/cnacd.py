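"""CNACD: unsupervised nuclei classification by automatic color deconvolution.

A single annotated pixel per nucleus is classified as immunopositive
(DAB-stained, brown) or immunonegative (hematoxylin only, blue) without any
training: the image's stain vectors are estimated automatically (SVD/angle
method; the default OD filter drops unstained background pixels, whose
projection angles are pure noise and would wreck the robust extremes on
images with a clean white background), the whole image is sparse-coded
against them (non-negative LASSO, lambda = 0.1), each stain's rank-1 OD
contribution is rendered back to RGB and collapsed to grayscale, and the
nucleus takes the label of whichever stain is *darker* (more stain = lower
grayscale) at its pixel. Ties go to immunopositive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .od import image_to_od_matrix, od_to_rgb
from .stains import MacenkoParams, macenko_stain_vectors, sparse_code

POSITIVE = "+"
NEGATIVE = "-"

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class NucleusAnnotation:
    """A point annotation: 0-based pixel coordinates (x = column, y = row)
    and an optional immunopositive (+) / immunonegative (-) label."""

    x: int
    y: int
    label: str | None = None


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def stain_grayscale_images(image: np.ndarray, lambda1: float = 0.1,
                           macenko_params: MacenkoParams | None = None):
    """Deconvolve an image and return (gray_negative, gray_positive) planes.

    Each stain's contribution is the rank-1 OD image V[:, j] (outer) S[j, :],
    inverted to RGB and reduced with fixed luma weights. Pass
    ``MacenkoParams(beta=None)`` to disable the OD background filter.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    od = image_to_od_matrix(image)
    basis = macenko_stain_vectors(od, macenko_params or MacenkoParams())
    S = sparse_code(od, basis, lambda1)
    grays = []
    for j in range(2):
        od_j = np.outer(basis.V[:, j], S[j])           # 3 x n
        rgb_j = od_to_rgb(od_j.T.reshape(h, w, 3))
        grays.append(rgb_j @ _LUMA)
    return grays[0], grays[1]


def classify_pixels(image: np.ndarray,
                    annotations: Iterable[NucleusAnnotation | tuple[int, int]],
                    lambda1: float = 0.1,
                    macenko_params: MacenkoParams | None = None) -> list[str]:
    """Predict +/- labels at the annotated pixels of an IHC image."""
    points = []
    for a in annotations:
        if isinstance(a, NucleusAnnotation):
            points.append((a.x, a.y))
        else:
            points.append((int(a[0]), int(a[1])))
    if not points:
        raise ValueError("need at least one annotation")
    h, w = np.asarray(image).shape[:2]
    for x, y in points:
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"annotation ({x}, {y}) outside image")
    gray_neg, gray_pos = stain_grayscale_images(image, lambda1, macenko_params)
    labels = []
    for x, y in points:
        # Lighter positive plane than negative plane means less DAB there.
        labels.append(NEGATIVE if gray_pos[y, x] > gray_neg[y, x] else POSITIVE)
    return labels


def accuracy(pred: Sequence[str], truth: Sequence[str]):
    """Classification accuracy AC = (TP + TN) / (TP + FN + TN + FP),
    with '+' as the positive class. Returns (fraction, ConfusionCounts)."""
    if len(pred) != len(truth):
        raise ValueError("prediction and truth lengths differ")
    if len(pred) == 0:
        raise ValueError("empty label lists")
    tp = sum(1 for p, t in zip(pred, truth) if p == POSITIVE and t == POSITIVE)
    tn = sum(1 for p, t in zip(pred, truth) if p == NEGATIVE and t == NEGATIVE)
    fp = sum(1 for p, t in zip(pred, truth) if p == POSITIVE and t == NEGATIVE)
    fn = sum(1 for p, t in zip(pred, truth) if p == NEGATIVE and t == POSITIVE)
    counts = ConfusionCounts(tp, tn, fp, fn)
    return (tp + tn) / counts.total, counts
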