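"""Pluggable segmentation interface.

A segmenter turns an image into editable AnnotationObjects — the same
records the annotator produces and the classifier consumes — so results
from any model can be corrected, measured, or classified downstream.
The built-in "reference" segmenter is a classical pipeline (Otsu threshold
on the channel mean, 4-connected components, small-object filter) that
exercises the contract without any pretrained weights.
"""

from __future__ import annotations

from typing import Optional, Protocol

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .annotator import mask_to_annotation
from .errors import ValidationError
from .project import AnnotationObject, ImageItem


class Segmenter(Protocol):
    def segment(self, image: ImageItem, z_index: int = 0) -> list[AnnotationObject]:
        """Return per-object annotations for one z-plane of an image."""
        ...


class ReferenceSegmenter:
    """Otsu threshold + connected components; bright objects on dark background."""

    def __init__(self, kind_id: str = "object", min_area: int = 4):
        self.kind_id = kind_id
        self.min_area = min_area

    def segment(self, image: ImageItem, z_index: int = 0) -> list[AnnotationObject]:
        plane = image.pixels[z_index].mean(axis=0)
        if np.ptp(plane) == 0:
            return []
        fg = plane > threshold_otsu(plane)
        labels, n = ndimage.label(
            fg, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        )
        out = []
        for k in range(1, n + 1):
            mask = labels == k
            if mask.sum() < self.min_area:
                continue
            out.append(
                mask_to_annotation(
                    mask,
                    image_id=image.id,
                    kind_id=self.kind_id,
                    category_id=None,
                    z_index=z_index,
                    annotation_id=f"{image.id}:seg:{z_index}:{k}",
                )
            )
        return out


SEGMENTERS: dict[str, type] = {"reference": ReferenceSegmenter}


def get_segmenter(name: str, **kwargs) -> Segmenter:
    if name not in SEGMENTERS:
        raise ValidationError(
            f"unknown segmenter {name!r}; available: {sorted(SEGMENTERS)}"
        )
    return SEGMENTERS[name](**kwargs)
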