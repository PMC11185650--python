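"""Zarr project archives: lossless save/load of the committed project state.

Layout (schema version "1"):

    /                  attrs: name, schema_version, kinds, categories
    /images/<id>       (z, c, y, x) float array; attrs: name, bit_depth,
                       kind_id, category_id, partition, channel_display
    /annotations/<id>  (h, w) uint8 mask; attrs: image_id, kind_id,
                       category_id, bbox, z_index, partition

Images are chunked by whole plane (1, 1, y, x).
"""

from __future__ import annotations

import numpy as np
import zarr

from ..errors import SchemaVersionError
from ..project import (
    AnnotationObject,
    Category,
    ChannelDisplay,
    ImageItem,
    Kind,
    Partition,
    Project,
)

SCHEMA_VERSION = "1"


def save_project(project: Project, path) -> None:
    """Serialize the committed state of a project to a Zarr archive."""
    root = zarr.open_group(str(path), mode="w")
    root.attrs["name"] = project.name
    root.attrs["schema_version"] = SCHEMA_VERSION
    root.attrs["kinds"] = [
        {"id": k.id, "name": k.name, "category_ids": list(k.category_ids)}
        for k in project.kinds(committed=True).values()
    ]
    root.attrs["categories"] = [
        {"id": c.id, "name": c.name, "color": list(c.color), "kind_id": c.kind_id}
        for c in project.categories(committed=True).values()
    ]
    images = root.create_group("images")
    for iid, item in sorted(project.images(committed=True).items()):
        z, c, h, w = item.pixels.shape
        arr = images.create_array(
            iid, shape=item.pixels.shape, dtype="f8", chunks=(1, 1, h, w)
        )
        arr[:] = item.pixels
        arr.attrs.update(
            name=item.name,
            bit_depth=item.bit_depth,
            kind_id=item.kind_id,
            category_id=item.category_id,
            partition=item.partition.value,
            channel_display=[
                {"visible": cd.visible, "color": list(cd.color)}
                for cd in item.channel_display
            ],
        )
    anns = root.create_group("annotations")
    for aid, ann in sorted(project.annotations(committed=True).items()):
        arr = anns.create_array(aid, shape=ann.mask.shape, dtype="u1")
        arr[:] = ann.mask.astype(np.uint8)
        arr.attrs.update(
            image_id=ann.image_id,
            kind_id=ann.kind_id,
            category_id=ann.category_id,
            bbox=list(ann.bbox),
            z_index=ann.z_index,
            partition=ann.partition.value,
        )


def load_project(path) -> Project:
    """Reconstruct a project from an archive; staged change set starts empty."""
    root = zarr.open_group(str(path), mode="r")
    version = root.attrs.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"archive schema version {version!r} is not supported "
            f"(expected {SCHEMA_VERSION!r})"
        )
    project = Project(root.attrs["name"])
    project._committed["kinds"] = {
        k["id"]: Kind(id=k["id"], name=k["name"], category_ids=list(k["category_ids"]))
        for k in root.attrs["kinds"]
    }
    project._committed["categories"] = {
        c["id"]: Category(
            id=c["id"], name=c["name"], color=tuple(c["color"]), kind_id=c["kind_id"]
        )
        for c in root.attrs["categories"]
    }
    if "images" in root:
        for iid in sorted(root["images"].array_keys()):
            arr = root["images"][iid]
            a = arr.attrs
            project._committed["images"][iid] = ImageItem(
                id=iid,
                name=a["name"],
                pixels=arr[:],
                bit_depth=int(a["bit_depth"]),
                kind_id=a["kind_id"],
                category_id=a["category_id"],
                partition=Partition(a["partition"]),
                channel_display=tuple(
                    ChannelDisplay(visible=cd["visible"], color=tuple(cd["color"]))
                    for cd in a["channel_display"]
                ),
            )
    if "annotations" in root:
        for aid in sorted(root["annotations"].array_keys()):
            arr = root["annotations"][aid]
            a = arr.attrs
            project._committed["annotations"][aid] = AnnotationObject(
                id=aid,
                image_id=a["image_id"],
                kind_id=a["kind_id"],
                category_id=a["category_id"],
                bbox=tuple(a["bbox"]),
                mask=arr[:].astype(bool),
                z_index=int(a["z_index"]),
                partition=Partition(a["partition"]),
            )
    return project
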