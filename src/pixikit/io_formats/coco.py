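"""COCO object-detection JSON interchange.

Masks are converted to polygons by tracing the pixel-corner boundary exactly:
each unit edge between a foreground pixel and background (or the image edge)
becomes a directed polygon edge, chained into closed loops (outer contours
plus one loop per hole).  Because vertices sit on pixel corners, rasterizing
the polygons back with the even-odd pixel-center rule reproduces the original
mask bit-exactly, so export -> import round trips are lossless.

Annotation ``area`` is the mask pixel count and ``bbox`` is [x, y, w, h] in
the COCO convention (0-based, half-open).  Entity string ids are mapped to
deterministic integer ids (sorted order, 1-based); the original ids ride
along in a ``pixikit_id`` field.
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np

from ..annotator import mask_to_annotation, points_in_polygon
from ..errors import ValidationError
from ..project import IMAGE_KIND, Project, create_project

# turn preference when chaining boundary edges: clockwise, straight, then
# counter-clockwise (y-down coords), which keeps diagonally-touching pixels
# in separate loops
def _turns(d: tuple[int, int]):
    dx, dy = d
    return ((-dy, dx), (dx, dy), (dy, -dx))


def trace_mask_polygons(mask: np.ndarray) -> list[list[tuple[float, float]]]:
    """Closed boundary loops of a binary mask at pixel-corner resolution."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValidationError("cannot trace an empty mask")
    h, w = m.shape
    padded = np.pad(m, 1, constant_values=False)
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add(a, b):
        edges.setdefault(a, []).append(b)

    rr, cc = np.nonzero(m)
    for r, c in zip(rr.tolist(), cc.tolist()):
        if not padded[r, c + 1]:      # bg above
            add((c, r), (c + 1, r))
        if not padded[r + 1, c + 2]:  # bg right
            add((c + 1, r), (c + 1, r + 1))
        if not padded[r + 2, c + 1]:  # bg below
            add((c + 1, r + 1), (c, r + 1))
        if not padded[r + 1, c]:      # bg left
            add((c, r + 1), (c, r))

    for v in edges.values():
        v.sort()
    loops: list[list[tuple[float, float]]] = []
    while edges:
        start = min(edges)
        loop = [start]
        prev_dir = None
        current = start
        while True:
            outs = edges[current]
            if prev_dir is None or len(outs) == 1:
                nxt = outs.pop(0)
            else:
                nxt = None
                for td in _turns(prev_dir):
                    cand = (current[0] + td[0], current[1] + td[1])
                    if cand in outs:
                        outs.remove(cand)
                        nxt = cand
                        break
                if nxt is None:
                    nxt = outs.pop(0)
            if not outs:
                del edges[current]
            prev_dir = (nxt[0] - current[0], nxt[1] - current[1])
            if nxt == start:
                break
            loop.append(nxt)
            current = nxt
        loops.append(_simplify(loop))
    return loops


def _simplify(loop: list[tuple[int, int]]) -> list[tuple[float, float]]:
    """Drop collinear intermediate vertices."""
    out = []
    n = len(loop)
    for i in range(n):
        a, b, c = loop[i - 1], loop[i], loop[(i + 1) % n]
        if (b[0] - a[0]) * (c[1] - b[1]) != (b[1] - a[1]) * (c[0] - b[0]):
            out.append((float(b[0]), float(b[1])))
    return out


def rasterize_polygons(
    loops: list[list[tuple[float, float]]], extent: tuple[int, int]
) -> np.ndarray:
    """Even-odd fill of a set of closed loops onto a pixel grid."""
    h, w = extent
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = xx + 0.5, yy + 0.5
    mask = np.zeros((h, w), dtype=bool)
    for loop in loops:
        mask ^= points_in_polygon(cx, cy, loop)
    return mask


# --------------------------------------------------------------------------
# document construction


def export_coco(project: Project, splits=None) -> dict:
    """Project annotations as a COCO object-detection document (dict)."""
    annotations = project.annotations()
    if splits is not None:
        keep = set()
        for split in splits:
            keep.update(project.select_split(split))
        annotations = {k: v for k, v in annotations.items() if k in keep}
    images = project.images()
    cats = project.categories()

    image_ids = {iid: i + 1 for i, iid in enumerate(sorted(images))}
    cat_ids = {cid: i + 1 for i, cid in enumerate(sorted(cats))}

    doc = {
        "info": {"description": project.name},
        "images": [
            {
                "id": image_ids[iid],
                "pixikit_id": iid,
                "file_name": images[iid].name,
                "width": images[iid].extent[1],
                "height": images[iid].extent[0],
            }
            for iid in sorted(images)
        ],
        "categories": [
            {
                "id": cat_ids[cid],
                "pixikit_id": cid,
                "name": cats[cid].name,
                "supercategory": cats[cid].kind_id,
            }
            for cid in sorted(cats)
        ],
        "annotations": [],
    }
    for n, aid in enumerate(sorted(annotations), start=1):
        ann = annotations[aid]
        x, y, w, h = ann.bbox
        full = np.zeros(images[ann.image_id].extent, dtype=bool)
        full[y : y + h, x : x + w] = ann.mask
        loops = trace_mask_polygons(full)
        doc["annotations"].append(
            {
                "id": n,
                "pixikit_id": aid,
                "image_id": image_ids[ann.image_id],
                "category_id": cat_ids[ann.category_id],
                "bbox": [x, y, w, h],
                "segmentation": [
                    [coord for pt in loop for coord in pt] for loop in loops
                ],
                "area": int(ann.mask.sum()),
                "iscrowd": 0,
            }
        )
    return doc


def import_coco(doc: dict, project: Optional[Project] = None) -> Project:
    """Rasterize a COCO document's polygon annotations into a project.

    Images already present in ``project`` (matched by name) are reused;
    otherwise blank placeholder images of the declared size are created.
    """
    from ..project import ImageItem

    if project is None:
        project = create_project(doc.get("info", {}).get("description") or "coco-import")
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise ValidationError(f"COCO document missing {key!r}")

    existing_by_name = {img.name: img.id for img in project.images().values()}
    image_map: dict[int, str] = {}
    extent_map: dict[int, tuple[int, int]] = {}
    for entry in doc["images"]:
        extent_map[entry["id"]] = (entry["height"], entry["width"])
        if entry["file_name"] in existing_by_name:
            image_map[entry["id"]] = existing_by_name[entry["file_name"]]
        else:
            iid = entry.get("pixikit_id", f"coco-img-{entry['id']}")
            pixels = np.zeros((1, 1, entry["height"], entry["width"]))
            project.add_images([ImageItem(id=iid, name=entry["file_name"], pixels=pixels)])
            image_map[entry["id"]] = iid

    kinds = project.kinds()
    cat_map: dict[int, str] = {}
    for entry in doc["categories"]:
        kind_name = entry.get("supercategory") or "object"
        if kind_name not in kinds:
            project.register_kind(kind_name)
            kinds = project.kinds()
        existing = {
            project.categories()[cid].name: cid
            for cid in kinds[kind_name].category_ids
        }
        if entry["name"] in existing:
            cat_map[entry["id"]] = existing[entry["name"]]
        else:
            cat = project.register_category(kind_name, entry["name"], (255, 255, 255))
            kinds = project.kinds()
            cat_map[entry["id"]] = cat.id

    for entry in doc["annotations"]:
        if entry["image_id"] not in image_map:
            raise ValidationError(
                f"annotation {entry['id']} references missing image {entry['image_id']}"
            )
        extent = extent_map[entry["image_id"]]
        loops = [
            list(zip(flat[0::2], flat[1::2])) for flat in entry["segmentation"]
        ]
        mask = rasterize_polygons(loops, extent)
        if not mask.any():
            raise ValidationError(f"annotation {entry['id']} rasterized to empty mask")
        cat_id = cat_map[entry["category_id"]]
        ann = mask_to_annotation(
            mask,
            image_id=image_map[entry["image_id"]],
            kind_id=project.categories()[cat_id].kind_id,
            category_id=cat_id,
            annotation_id=entry.get("pixikit_id", f"coco-ann-{entry['id']}"),
        )
        project.add_annotations([ann])
    return project


def write_coco_json(doc: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def read_coco_json(path) -> dict:
    with open(path) as fh:
        try:
            return json.load(fh)
        except json.JSONDecodeError as err:
            raise ValidationError(f"malformed COCO JSON: {err}") from err
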