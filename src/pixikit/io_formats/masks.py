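"""Mask exporters: labeled instance, binary instance, binary semantic PNGs."""

from __future__ import annotations

import os
import warnings

import imageio.v3 as iio
import numpy as np

from ..annotator import annotation_to_full_mask
from ..errors import ValidationError
from ..project import Project, Split


def export_masks(project: Project, split: Split, mode: str, out_dir) -> dict[str, np.ndarray]:
    """Write mask images for a split of objects; returns {path: array}.

    labeled_instance: one uint16 image per source image, pixel value =
    instance index (1..n by annotation id order, 0 = background); overlapping
    instances resolve to the later draw (a warning is emitted).
    binary_instance: one binary image per object.
    binary_semantic: one binary image per (source image, category), the union
    of that category's objects.
    """
    ann_ids = project.select_split(split)
    if not ann_ids:
        raise ValidationError("split contains no objects")
    annotations = project.annotations()
    images = project.images()
    cats = project.categories()
    os.makedirs(out_dir, exist_ok=True)
    written: dict[str, np.ndarray] = {}

    by_image: dict[str, list[str]] = {}
    for aid in ann_ids:
        by_image.setdefault(annotations[aid].image_id, []).append(aid)

    if mode == "labeled_instance":
        for iid in sorted(by_image):
            extent = images[iid].extent
            out = np.zeros(extent, dtype=np.uint16)
            for index, aid in enumerate(sorted(by_image[iid]), start=1):
                full = annotation_to_full_mask(annotations[aid], extent)
                if (out[full] != 0).any():
                    warnings.warn(
                        f"overlapping instances in image {iid!r}: later instance wins",
                        stacklevel=2,
                    )
                out[full] = index
            path = os.path.join(out_dir, f"{iid}_labeled.png")
            iio.imwrite(path, out)
            written[path] = out
    elif mode == "binary_instance":
        for aid in ann_ids:
            ann = annotations[aid]
            full = annotation_to_full_mask(ann, images[ann.image_id].extent)
            path = os.path.join(out_dir, f"{aid.replace(':', '_')}.png")
            arr = (full * np.uint8(255))
            iio.imwrite(path, arr)
            written[path] = arr
    elif mode == "binary_semantic":
        for iid in sorted(by_image):
            extent = images[iid].extent
            by_cat: dict[str, np.ndarray] = {}
            for aid in sorted(by_image[iid]):
                ann = annotations[aid]
                acc = by_cat.setdefault(ann.category_id, np.zeros(extent, dtype=bool))
                acc |= annotation_to_full_mask(ann, extent)
            for cid in sorted(by_cat):
                cat_name = cats[cid].name
                path = os.path.join(out_dir, f"{iid}_{cat_name}.png")
                arr = by_cat[cid].astype(np.uint8) * 255
                iio.imwrite(path, arr)
                written[path] = arr
    else:
        raise ValidationError(
            "mode must be labeled_instance, binary_instance, or binary_semantic"
        )
    return written
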