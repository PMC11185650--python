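"""Annotation operators: geometric shapes, SLIC quick-select, flood fill,
threshold selection, and mask arithmetic.

Every operator acts on a single z-slice, passed as a (channel, y, x) array of
[0, 1] intensities, and returns a full-extent boolean mask.  Masks become
:class:`~pixikit.project.AnnotationObject` records via
:func:`mask_to_annotation`, which crops to the tight bounding box.

Rasterization uses the pixel-center inside test: the pixel at (row r, col c)
has its center at (x, y) = (c + 0.5, r + 0.5), and polygons are filled with
the even-odd rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import EmptyAnnotationError, ValidationError
from .project import AnnotationObject, Partition


# --------------------------------------------------------------------------
# geometric shapes


@dataclass(frozen=True)
class ShapeSpec:
    """A rectangle, ellipse, or polygon in pixel coordinates.

    rectangle: params = (x, y, width, height), half-open.
    ellipse:   params = (center_x, center_y, radius_x, radius_y).
    polygon:   params = ordered vertex sequence [(x0, y0), ...], >= 3 vertices.
    """

    kind: Literal["rectangle", "ellipse", "polygon"]
    params: tuple

    def __post_init__(self) -> None:
        if self.kind == "rectangle":
            x, y, w, h = self.params
            if w <= 0 or h <= 0:
                raise ValidationError("rectangle width/height must be positive")
        elif self.kind == "ellipse":
            cx, cy, rx, ry = self.params
            if rx <= 0 or ry <= 0:
                raise ValidationError("ellipse radii must be positive")
        elif self.kind == "polygon":
            if len(self.params) < 3:
                raise ValidationError("polygon needs >= 3 vertices")
        else:
            raise ValidationError(f"unknown shape kind {self.kind!r}")


def points_in_polygon(px: np.ndarray, py: np.ndarray, vertices) -> np.ndarray:
    """Even-odd ray-casting test for arrays of points against one closed loop."""
    vx = np.asarray([v[0] for v in vertices], dtype=float)
    vy = np.asarray([v[1] for v in vertices], dtype=float)
    inside = np.zeros(px.shape, dtype=bool)
    n = len(vx)
    j = n - 1
    for i in range(n):
        x1, y1, x2, y2 = vx[j], vy[j], vx[i], vy[i]
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < np.where(crosses, xint, np.inf))
        j = i
    return inside


def rasterize_shape(shape: ShapeSpec, image_extent: tuple[int, int]) -> np.ndarray:
    """Full-extent boolean mask of pixels whose centers lie inside the shape."""
    h, w = image_extent
    yy, xx = np.mgrid[0:h, 0:w]
    cx = xx + 0.5
    cy = yy + 0.5
    if shape.kind == "rectangle":
        x, y, rw, rh = shape.params
        mask = (cx >= x) & (cx < x + rw) & (cy >= y) & (cy < y + rh)
    elif shape.kind == "ellipse":
        ex, ey, rx, ry = shape.params
        mask = ((cx - ex) / rx) ** 2 + ((cy - ey) / ry) ** 2 <= 1.0
    else:
        mask = points_in_polygon(cx, cy, shape.params)
    if not mask.any():
        raise EmptyAnnotationError(f"{shape.kind} covers no pixel center in extent {image_extent}")
    return mask


# --------------------------------------------------------------------------
# SLIC superpixels

@dataclass(frozen=True)
class SuperpixelMap:
    """Partition of a slice into spatially compact, color-homogeneous regions."""

    labels: np.ndarray  # 2-axis int array, labels 1..k, every pixel labeled
    n_segments_requested: int
    compactness: float


def _slic_grid_centers(h: int, w: int, n: int) -> np.ndarray:
    """Deterministic grid of n seed centers, aspect-balanced."""
    rows = max(1, int(round(np.sqrt(n * h / w))))
    rows = min(rows, n)
    cols = int(np.ceil(n / rows))
    centers = []
    for r in range(rows):
        for c in range(cols):
            if len(centers) == n:
                break
            centers.append(((r + 0.5) * h / rows, (c + 0.5) * w / cols))
    return np.asarray(centers, dtype=float)


def compute_superpixels(
    slice_pixels: np.ndarray, n_segments: int, compactness: float = 10.0,
    n_iter: int = 5,
) -> SuperpixelMap:
    """SLIC superpixels of a (channel, y, x) slice.

    Localized k-means in (color, position) space: seeds start on a regular
    grid with spacing S = sqrt(h*w / n_segments); each iteration assigns
    pixels within a 2S window of each center using the distance
    d = d_color + (compactness / S) * d_space, then recenters.  Deterministic
    for fixed inputs (grid initialization, no random restarts).
    """
    pix = np.asarray(slice_pixels, dtype=float)
    if pix.ndim == 2:
        pix = pix[None]
    c, h, w = pix.shape
    if not (1 <= n_segments <= h * w):
        raise ValidationError(f"n_segments must be in [1, {h * w}], got {n_segments}")
    if n_segments == 1:
        return SuperpixelMap(np.ones((h, w), dtype=int), 1, float(compactness))

    s = np.sqrt(h * w / n_segments)
    ratio = compactness / s
    centers_sp = _slic_grid_centers(h, w, n_segments)  # (k, 2) as (y, x)
    yy, xx = np.mgrid[0:h, 0:w]
    feat = pix.reshape(c, -1).T  # (h*w, c)
    centers_col = np.empty((n_segments, c))
    for k, (cy_, cx_) in enumerate(centers_sp):
        centers_col[k] = pix[:, int(cy_), int(cx_)]

    labels = np.full((h, w), -1, dtype=int)
    for _ in range(n_iter):
        dist = np.full((h, w), np.inf)
        labels.fill(-1)
        for k in range(n_segments):
            cy_, cx_ = centers_sp[k]
            y0, y1 = max(0, int(cy_ - 2 * s)), min(h, int(cy_ + 2 * s) + 1)
            x0, x1 = max(0, int(cx_ - 2 * s)), min(w, int(cx_ + 2 * s) + 1)
            win = pix[:, y0:y1, x0:x1]
            dc2 = ((win - centers_col[k][:, None, None]) ** 2).sum(axis=0)
            ds2 = (yy[y0:y1, x0:x1] - cy_) ** 2 + (xx[y0:y1, x0:x1] - cx_) ** 2
            d = np.sqrt(dc2) + ratio * np.sqrt(ds2)
            sub = dist[y0:y1, x0:x1]
            better = d < sub
            sub[better] = d[better]
            lab_sub = labels[y0:y1, x0:x1]
            lab_sub[better] = k
        # orphans outside every window: nearest grid center by position
        if (labels < 0).any():
            orphan = labels < 0
            oy, ox = np.nonzero(orphan)
            d2 = (oy[:, None] - centers_sp[:, 0]) ** 2 + (ox[:, None] - centers_sp[:, 1]) ** 2
            labels[oy, ox] = d2.argmin(axis=1)
        flat = labels.ravel()
        for k in range(n_segments):
            sel = flat == k
            if sel.any():
                centers_sp[k] = (yy.ravel()[sel].mean(), xx.ravel()[sel].mean())
                centers_col[k] = feat[sel].mean(axis=0)

    # guarantee a partition with every label nonempty
    present = np.unique(labels)
    if len(present) < n_segments:
        missing = sorted(set(range(n_segments)) - set(present.tolist()))
        for k in missing:
            cy_, cx_ = centers_sp[k]
            d2 = (yy - cy_) ** 2 + (xx - cx_) ** 2
            # only steal from labels that keep >= 2 pixels
            counts = np.bincount(labels.ravel(), minlength=n_segments)
            order = np.argsort(d2.ravel())
            for idx in order:
                r, cc = divmod(idx, w)
                if counts[labels[r, cc]] > 1:
                    counts[labels[r, cc]] -= 1
                    labels[r, cc] = k
                    break
    return SuperpixelMap(labels + 1, n_segments, float(compactness))


def quick_select(
    superpixels: SuperpixelMap, seed_points: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Union of the superpixels containing each (x, y) seed point."""
    labels = superpixels.labels
    h, w = labels.shape
    wanted = set()
    for x, y in seed_points:
        if not (0 <= x < w and 0 <= y < h):
            raise ValidationError(f"seed ({x}, {y}) outside extent {(h, w)}")
        wanted.add(int(labels[int(y), int(x)]))
    return np.isin(labels, sorted(wanted))


# --------------------------------------------------------------------------
# flood fill / threshold


def flood_fill_select(
    slice_pixels: np.ndarray, seed: tuple[int, int], tolerance: float
) -> np.ndarray:
    """4-connected region reachable from the seed with color distance <= tolerance.

    Color distance is Euclidean over the channel axis of [0, 1] intensities.
    """
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")
    pix = np.asarray(slice_pixels, dtype=float)
    if pix.ndim == 2:
        pix = pix[None]
    _, h, w = pix.shape
    x, y = seed
    if not (0 <= x < w and 0 <= y < h):
        raise ValidationError(f"seed ({x}, {y}) outside extent {(h, w)}")
    seed_color = pix[:, int(y), int(x)]
    dist = np.sqrt(((pix - seed_color[:, None, None]) ** 2).sum(axis=0))
    within = dist <= tolerance + 1e-12
    labels, _ = ndimage.label(within, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    return labels == labels[int(y), int(x)]


def threshold_select(
    slice_pixels: np.ndarray,
    bbox: tuple[int, int, int, int],
    threshold: float,
    polarity: Literal["below", "above"] = "below",
) -> np.ndarray:
    """Pixels inside bbox whose channel-mean intensity is below/above threshold."""
    pix = np.asarray(slice_pixels, dtype=float)
    if pix.ndim == 2:
        pix = pix[None]
    _, h, w = pix.shape
    x, y, bw, bh = bbox
    if bw <= 0 or bh <= 0:
        raise ValidationError(f"degenerate bbox {bbox}")
    if x < 0 or y < 0 or x + bw > w or y + bh > h:
        raise ValidationError(f"bbox {bbox} outside extent {(h, w)}")
    mean = pix.mean(axis=0)
    mask = np.zeros((h, w), dtype=bool)
    window = mean[y : y + bh, x : x + bw]
    if polarity == "below":
        mask[y : y + bh, x : x + bw] = window < threshold
    elif polarity == "above":
        mask[y : y + bh, x : x + bw] = window > threshold
    else:
        raise ValidationError(f"polarity must be 'below' or 'above', got {polarity!r}")
    return mask


# --------------------------------------------------------------------------
# mask algebra and annotation construction


def combine_masks(
    base: np.ndarray, edit: np.ndarray, mode: Literal["add", "subtract"]
) -> np.ndarray:
    if base.shape != edit.shape:
        raise ValidationError(f"extent mismatch: {base.shape} vs {edit.shape}")
    base = np.asarray(base, dtype=bool)
    edit = np.asarray(edit, dtype=bool)
    if mode == "add":
        return base | edit
    if mode == "subtract":
        return base & ~edit
    raise ValidationError(f"mode must be 'add' or 'subtract', got {mode!r}")


def tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """(x, y, width, height) of the tight box around a nonempty mask."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise EmptyAnnotationError("mask has no foreground pixel")
    y0, y1 = int(rows[0]), int(rows[-1]) + 1
    x0, x1 = int(cols[0]), int(cols[-1]) + 1
    return (x0, y0, x1 - x0, y1 - y0)


def mask_to_annotation(
    mask: np.ndarray,
    image_id: str,
    kind_id: str,
    category_id: Optional[str],
    z_index: int = 0,
    annotation_id: Optional[str] = None,
    partition: Partition = Partition.UNASSIGNED,
) -> AnnotationObject:
    """Crop a full-extent mask to its tight bounding box as an AnnotationObject."""
    mask = np.asarray(mask, dtype=bool)
    x, y, w, h = tight_bbox(mask)
    if annotation_id is None:
        annotation_id = f"{image_id}:ann:{x}:{y}:{z_index}"
    return AnnotationObject(
        id=annotation_id,
        image_id=image_id,
        kind_id=kind_id,
        category_id=category_id,
        bbox=(x, y, w, h),
        mask=mask[y : y + h, x : x + w].copy(),
        z_index=z_index,
        partition=partition,
    )


def annotation_to_full_mask(
    annotation: AnnotationObject, image_extent: tuple[int, int]
) -> np.ndarray:
    """Reinflate a cropped annotation mask to full image extent."""
    h, w = image_extent
    out = np.zeros((h, w), dtype=bool)
    x, y, bw, bh = annotation.bbox
    out[y : y + bh, x : x + bw] = annotation.mask
    return out
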