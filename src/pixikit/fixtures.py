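"""Synthetic images, masks, and labeled datasets with known ground truth.

Every generator is a pure function of its spec and seed, so tests and demos
are reproducible without downloading any dataset.  Scenes place geometric
objects (disks, rectangles, plus signs) whose analytic geometry is known in
closed form, alongside the rasterized masks actually rendered; class datasets
produce images whose classes differ in mean intensity and in the frequency of
a sinusoidal texture, with additive Gaussian noise clipped to [0, 1] — the
simplest structure that makes both intensity- and texture-based
classification learnable and analyzable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import tifffile

from .annotator import ShapeSpec, combine_masks, mask_to_annotation, rasterize_shape
from .errors import ValidationError
from .measurements import GeometryRecord, derived_geometry, mask_geometry
from .project import AnnotationObject, ImageItem


# --------------------------------------------------------------------------
# shape scenes


@dataclass(frozen=True)
class SceneObject:
    """One object in a scene.

    shape: "disk" (params: center_x, center_y, radius),
           "rectangle" (params: x, y, width, height),
           "plus" (params: center_x, center_y, arm_length, thickness).
    channel_profile scales the object intensity per channel (default: all 1).
    """

    shape: str
    params: tuple
    intensity: float = 0.8
    channel_profile: Optional[tuple[float, ...]] = None


@dataclass(frozen=True)
class SceneSpec:
    extent: tuple[int, int] = (64, 64)
    objects: tuple[SceneObject, ...] = ()
    background: float = 0.1
    noise_sigma: float = 0.0
    n_channels: int = 1
    seed: int = 0
    require_disjoint: bool = True

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if not (0.0 <= self.background <= 1.0):
            raise ValidationError("background intensity must lie in [0, 1]")


@dataclass
class Scene:
    image: ImageItem
    annotations: list[AnnotationObject]
    analytic_geometry: list[GeometryRecord]
    raster_geometry: list[GeometryRecord]
    masks: list[np.ndarray]  # full-extent, one per object


def _object_mask(obj: SceneObject, extent: tuple[int, int]) -> np.ndarray:
    if obj.shape == "disk":
        cx, cy, r = obj.params
        return rasterize_shape(ShapeSpec("ellipse", (cx, cy, r, r)), extent)
    if obj.shape == "rectangle":
        return rasterize_shape(ShapeSpec("rectangle", tuple(obj.params)), extent)
    if obj.shape == "plus":
        cx, cy, arm, t = obj.params
        horiz = rasterize_shape(
            ShapeSpec("rectangle", (cx - arm / 2, cy - t / 2, arm, t)), extent
        )
        vert = rasterize_shape(
            ShapeSpec("rectangle", (cx - t / 2, cy - arm / 2, t, arm)), extent
        )
        return combine_masks(horiz, vert, "add")
    raise ValidationError(f"unknown scene shape {obj.shape!r}")


def _analytic_geometry(obj: SceneObject) -> GeometryRecord:
    """Closed-form area/perimeter/bbox of the continuous shape."""
    if obj.shape == "disk":
        _, _, r = obj.params
        return derived_geometry(math.pi * r**2, 2 * math.pi * r, (2 * r) ** 2)
    if obj.shape == "rectangle":
        _, _, w, h = obj.params
        return derived_geometry(w * h, 2 * (w + h), w * h)
    if obj.shape == "plus":
        _, _, arm, t = obj.params
        # two crossed arm x t bars sharing a t x t center; outline length 4*arm
        return derived_geometry(2 * arm * t - t**2, 4 * arm, arm * arm)
    raise ValidationError(f"unknown scene shape {obj.shape!r}")


def generate_shape_scene(spec: SceneSpec, image_id: str = "scene") -> Scene:
    """Render a scene: image + exact per-object masks + geometry both ways."""
    h, w = spec.extent
    rng = np.random.default_rng(spec.seed)
    masks = [_object_mask(obj, spec.extent) for obj in spec.objects]
    if spec.require_disjoint and len(masks) > 1:
        total = np.zeros((h, w), dtype=int)
        for m in masks:
            total += m
        if (total > 1).any():
            raise ValidationError("scene objects overlap but disjointness was requested")

    pixels = np.full((1, spec.n_channels, h, w), spec.background, dtype=float)
    for obj, mask in zip(spec.objects, masks):
        profile = obj.channel_profile or (1.0,) * spec.n_channels
        if len(profile) != spec.n_channels:
            raise ValidationError("channel_profile length must match n_channels")
        for ch, scale in enumerate(profile):
            plane = pixels[0, ch]
            plane[mask] = obj.intensity * scale
    if spec.noise_sigma > 0:
        pixels = pixels + rng.normal(0.0, spec.noise_sigma, size=pixels.shape)
    pixels = np.clip(pixels, 0.0, 1.0)

    image = ImageItem(id=image_id, name=image_id, pixels=pixels, bit_depth=8)
    annotations = [
        mask_to_annotation(mask, image_id, kind_id="object", category_id=None,
                           annotation_id=f"{image_id}:obj{i}")
        for i, mask in enumerate(masks)
    ]
    return Scene(
        image=image,
        annotations=annotations,
        analytic_geometry=[_analytic_geometry(o) for o in spec.objects],
        raster_geometry=[mask_geometry(m) for m in masks],
        masks=masks,
    )


def plus_sign_mask(arm: int = 9, thickness: int = 3) -> np.ndarray:
    """The irregular plus-sign fixture: two crossed arm x thickness bars."""
    m = np.zeros((arm, arm), dtype=bool)
    lo = (arm - thickness) // 2
    m[lo : lo + thickness, :] = True
    m[:, lo : lo + thickness] = True
    return m


# --------------------------------------------------------------------------
# class-separable labeled datasets


@dataclass(frozen=True)
class ClassSpec:
    mean_intensity: float
    texture_frequency: float  # cycles across the image diagonal
    texture_amplitude: float = 0.08


# Documented default study conditions: two classes separated both in mean
# intensity (0.3 vs 0.7) and texture frequency, noise sigma 0.1.
DEFAULT_CLASS_SPECS = (
    ClassSpec(mean_intensity=0.3, texture_frequency=2.0),
    ClassSpec(mean_intensity=0.7, texture_frequency=6.0),
)


@dataclass
class ClassDataset:
    items: list[ImageItem]
    labels: list[str]  # class name per item, aligned with items
    class_names: tuple[str, ...]
    class_specs: tuple[ClassSpec, ...]


def generate_class_dataset(
    n_per_class: int,
    class_specs: Sequence[ClassSpec] = DEFAULT_CLASS_SPECS,
    noise_sigma: float = 0.1,
    extent: tuple[int, int] = (32, 32),
    seed: int = 0,
    class_names: Optional[Sequence[str]] = None,
) -> ClassDataset:
    """Balanced labeled image set with class-specific intensity and texture."""
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    if len(class_specs) < 2:
        raise ValidationError("need at least 2 class specs")
    if len(set(class_specs)) < len(class_specs):
        warnings.warn("identical class specs: classes are not separable", stacklevel=2)
    if class_names is None:
        class_names = tuple(f"class{i}" for i in range(len(class_specs)))
    h, w = extent
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    diag = (xx + yy) / (h + w)
    items: list[ImageItem] = []
    labels: list[str] = []
    for ci, spec in enumerate(class_specs):
        for j in range(n_per_class):
            phase = rng.uniform(0, 2 * math.pi)
            tex = spec.texture_amplitude * np.sin(
                2 * math.pi * spec.texture_frequency * diag + phase
            )
            img = spec.mean_intensity + tex + rng.normal(0, noise_sigma, size=(h, w))
            img = np.clip(img, 0.0, 1.0)[None, None]
            item_id = f"{class_names[ci]}-{j:03d}"
            items.append(ImageItem(id=item_id, name=item_id, pixels=img, bit_depth=8))
            labels.append(class_names[ci])
    return ClassDataset(
        items=items,
        labels=labels,
        class_names=tuple(class_names),
        class_specs=tuple(class_specs),
    )


# --------------------------------------------------------------------------
# hyperstack TIFFs


def generate_hyperstack(
    path,
    z: int,
    channels: int,
    extent: tuple[int, int] = (16, 16),
    seed: int = 0,
) -> np.ndarray:
    """Write a z*channels-page uint8 TIFF (channel fastest within each z plane).

    Returns the (z, channels, h, w) array that was written.
    """
    if z < 1 or channels < 1:
        raise ValidationError("z and channels must be >= 1")
    h, w = extent
    rng = np.random.default_rng(seed)
    data = rng.integers(0, 256, size=(z, channels, h, w), dtype=np.uint8)
    tifffile.imwrite(path, data.reshape(z * channels, h, w), photometric="minisblack")
    return data
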