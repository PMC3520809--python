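"""Collagen quantification from stained-section field images.

Emulates the morphometric workflow of the study: for each heart, ten
randomly selected fields across the left-ventricular wall are imaged after
picrosirius-red staining; collagen-positive area is segmented by a global
intensity threshold on the stain channel (Otsu's threshold by default,
standing in for the interactive colour thresholding of the original
morphometry software) and expressed as a percentage of the measured area.
The heart-level value is the unweighted mean over fields (fields are
equal-sized).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .errors import InputError

#: Fields analyzed per heart.
N_FIELDS = 10


@dataclass
class HistologyField:
    """One stained field: stain-channel image plus its collagen mask."""

    image: np.ndarray
    mask: Optional[np.ndarray]
    field_id: int
    animal_id: int | str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2 or self.image.size == 0:
            raise InputError("field image must be a non-empty 2-D array")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.image.shape:
                raise InputError("mask shape must match image shape")


@dataclass
class CollagenResult:
    """Per-field and heart-level collagen area fractions (%)."""

    per_field_pct: List[float]
    heart_pct: float
    n_fields: int


def segment_collagen(image: np.ndarray, threshold: Optional[float] = None) -> np.ndarray:
    """Binary collagen mask: pixels with stain intensity >= threshold.

    With ``threshold=None`` the global Otsu threshold of the image is used.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise InputError("empty image")
    if not np.all(np.isfinite(img)):
        raise InputError("image contains non-finite values")
    if threshold is None:
        if np.ptp(img) == 0:
            # Degenerate uniform field: nothing separable, call it background.
            return np.zeros_like(img, dtype=bool)
        threshold = float(threshold_otsu(img))
    return img >= threshold


def field_percent(mask: np.ndarray) -> float:
    """Collagen-positive percentage of one field's measured area."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        raise InputError("zero-pixel field")
    return 100.0 * float(m.sum()) / m.size


def collagen_percent(fields: Sequence[HistologyField]) -> CollagenResult:
    """Heart-level collagen percentage from 1-10 segmented fields.

    Fields whose mask is missing are segmented with the default (Otsu)
    threshold first.
    """
    if not 1 <= len(fields) <= N_FIELDS:
        raise InputError(f"expected 1-{N_FIELDS} fields, got {len(fields)}")
    per_field = []
    for f in fields:
        mask = f.mask if f.mask is not None else segment_collagen(f.image)
        per_field.append(field_percent(mask))
    return CollagenResult(
        per_field_pct=per_field,
        heart_pct=float(np.mean(per_field)),
        n_fields=len(per_field),
    )


def batch_threshold(images: Sequence[np.ndarray], subsample: int = 4) -> float:
    """Single staining-batch threshold: Otsu on the pooled field histogram.

    Thresholding each field (or heart) separately is unreliable when a field
    is almost collagen-free — with extreme class imbalance Otsu splits the
    background mode instead of separating stain from background. Pooling all
    fields of a staining batch keeps both intensity modes well represented,
    the way an operator calibrates one colour threshold per batch and applies
    it to every section.
    """
    if not images:
        raise InputError("no images to pool")
    pooled = np.concatenate(
        [np.asarray(img, dtype=float).ravel()[::subsample] for img in images]
    )
    if np.ptp(pooled) == 0:
        # uniform batch: nothing separable, threshold above the single level
        return float(pooled[0]) + 1.0
    return float(threshold_otsu(pooled))


def quantify_heart(
    images: Sequence[np.ndarray], threshold: Optional[float] = None
) -> CollagenResult:
    """Segment each field image and aggregate to the heart-level collagen %."""
    fields = [
        HistologyField(image=img, mask=segment_collagen(img, threshold), field_id=i + 1)
        for i, img in enumerate(images)
    ]
    return collagen_percent(fields)
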