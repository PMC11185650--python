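"""In-memory project store: images, kinds, categories, annotations, partitions.

The store keeps a *committed* state plus a staged change set holding only the
edits made since the last commit (per-entity field diffs).  Every read goes
through the staged view by default, so downstream code (measurements,
training) always sees the researcher's current working state; ``commit``
folds the change set into the committed state and ``revert`` discards it,
restoring the last committed state exactly.

Coordinates are 0-based with half-open intervals, x to the right and y down,
matching the COCO convention used on export.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ConflictError, ValidationError

IMAGE_KIND = "Image"
UNKNOWN_CATEGORY_NAME = "Unknown"


class Partition(str, Enum):
    """An item's role in model development."""

    TRAIN = "train"
    VALIDATION = "validation"
    INFERENCE = "inference"
    UNASSIGNED = "unassigned"


def _freeze(arr: np.ndarray) -> np.ndarray:
    """Return a read-only view so in-place mutation cannot bypass staging."""
    arr = np.asarray(arr)
    arr.setflags(write=False)
    return arr


@dataclass(frozen=True)
class ChannelDisplay:
    visible: bool = True
    color: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass
class ImageItem:
    """A multichannel, optionally z-stacked raster.

    ``pixels`` is a 4-axis float array ordered (z, channel, y, x) with
    intensities normalized to [0, 1] by the source bit depth.
    """

    id: str
    name: str
    pixels: np.ndarray
    bit_depth: int = 8
    kind_id: str = IMAGE_KIND
    category_id: Optional[str] = None
    partition: Partition = Partition.UNASSIGNED
    channel_display: tuple[ChannelDisplay, ...] = ()

    def __post_init__(self) -> None:
        self.pixels = _freeze(np.asarray(self.pixels, dtype=float))
        if not self.channel_display and self.pixels.ndim == 4:
            self.channel_display = tuple(
                ChannelDisplay() for _ in range(self.pixels.shape[1])
            )
        self.partition = Partition(self.partition)

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def extent(self) -> tuple[int, int]:
        """(height, width) of each plane."""
        return self.pixels.shape[2], self.pixels.shape[3]

    @property
    def data_token(self) -> int:
        """Identity token of the pixel buffer; changes iff pixels are replaced."""
        return id(self.pixels)

    def validate(self) -> None:
        if self.pixels.ndim != 4 or min(self.pixels.shape) < 1:
            raise ValidationError(
                f"image {self.id!r}: pixels must be a (z, channel, y, x) array "
                f"with all axes >= 1, got shape {self.pixels.shape}"
            )
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValidationError(f"image {self.id!r}: intensities outside [0, 1]")
        if len(self.channel_display) != self.pixels.shape[1]:
            raise ValidationError(
                f"image {self.id!r}: channel_display length "
                f"{len(self.channel_display)} != channel count {self.pixels.shape[1]}"
            )


@dataclass
class AnnotationObject:
    """A per-object binary mask cropped to a tight bounding box."""

    id: str
    image_id: str
    kind_id: str
    category_id: Optional[str]
    bbox: tuple[int, int, int, int]  # (x, y, width, height), half-open
    mask: np.ndarray  # bool, shape (height, width)
    z_index: int = 0
    partition: Partition = Partition.UNASSIGNED

    def __post_init__(self) -> None:
        self.mask = _freeze(np.asarray(self.mask, dtype=bool))
        self.bbox = tuple(int(v) for v in self.bbox)
        self.partition = Partition(self.partition)

    @property
    def data_token(self) -> int:
        return id(self.mask)

    def validate(self, image_extent: Optional[tuple[int, int]] = None) -> None:
        x, y, w, h = self.bbox
        if w <= 0 or h <= 0:
            raise ValidationError(f"annotation {self.id!r}: degenerate bbox {self.bbox}")
        if self.mask.shape != (h, w):
            raise ValidationError(
                f"annotation {self.id!r}: mask shape {self.mask.shape} != (h, w) = {(h, w)}"
            )
        if not self.mask.any():
            raise ValidationError(f"annotation {self.id!r}: mask has no foreground")
        rows = self.mask.any(axis=1)
        cols = self.mask.any(axis=0)
        if not (rows[0] and rows[-1] and cols[0] and cols[-1]):
            raise ValidationError(f"annotation {self.id!r}: bbox is not tight")
        if image_extent is not None:
            ih, iw = image_extent
            if x < 0 or y < 0 or x + w > iw or y + h > ih:
                raise ValidationError(
                    f"annotation {self.id!r}: bbox {self.bbox} outside image "
                    f"extent {(ih, iw)}"
                )


@dataclass
class Kind:
    id: str
    name: str
    category_ids: list[str] = field(default_factory=list)


@dataclass
class Category:
    id: str
    name: str
    color: tuple[int, int, int]
    kind_id: str


@dataclass(frozen=True)
class Split:
    """Selection of items by kind, optionally narrowed by category/partition.

    An empty (None) category or partition filter means "all".
    """

    kind_id: str
    category_ids: Optional[frozenset[str]] = None
    partitions: Optional[frozenset[Partition]] = None

    def __post_init__(self) -> None:
        if self.category_ids is not None:
            object.__setattr__(self, "category_ids", frozenset(self.category_ids))
        if self.partitions is not None:
            object.__setattr__(
                self, "partitions", frozenset(Partition(p) for p in self.partitions)
            )


_COLLECTIONS = ("images", "annotations", "kinds", "categories")


def _unknown_category_id(kind_id: str) -> str:
    return f"{kind_id}::{UNKNOWN_CATEGORY_NAME}"


class Project:
    """Entity store with staged (uncommitted) edits.

    Entities live in id-keyed tables.  Edits accumulate in a change set
    (added entities, per-field diffs on existing ones) until :meth:`commit`
    folds them into the committed tables or :meth:`revert` drops them.
    """

    def __init__(self, name: str):
        if not name:
            raise ValidationError("project name must be nonempty")
        self.name = name
        self._committed: dict[str, dict] = {c: {} for c in _COLLECTIONS}
        self._added: dict[str, dict] = {c: {} for c in _COLLECTIONS}
        self._updated: dict[str, dict] = {c: {} for c in _COLLECTIONS}
        # The built-in kinds/categories are part of the initial committed state.
        image_kind = Kind(id=IMAGE_KIND, name=IMAGE_KIND)
        self._committed["kinds"][IMAGE_KIND] = image_kind
        unk = Category(
            id=_unknown_category_id(IMAGE_KIND),
            name=UNKNOWN_CATEGORY_NAME,
            color=(128, 128, 128),
            kind_id=IMAGE_KIND,
        )
        self._committed["categories"][unk.id] = unk
        image_kind.category_ids.append(unk.id)

    # -- reads ------------------------------------------------------------

    def _view(self, coll: str, committed: bool = False) -> dict:
        base = self._committed[coll]
        if committed:
            return dict(base)
        out = dict(base)
        out.update(self._added[coll])
        for eid, diff in self._updated[coll].items():
            out[eid] = replace(out[eid], **diff)
        return out

    def images(self, committed: bool = False) -> dict[str, ImageItem]:
        return self._view("images", committed)

    def annotations(self, committed: bool = False) -> dict[str, AnnotationObject]:
        return self._view("annotations", committed)

    def kinds(self, committed: bool = False) -> dict[str, Kind]:
        return self._view("kinds", committed)

    def categories(self, committed: bool = False) -> dict[str, Category]:
        return self._view("categories", committed)

    def get(self, item_id: str, committed: bool = False):
        for coll in _COLLECTIONS:
            view = self._view(coll, committed)
            if item_id in view:
                return view[item_id]
        raise ValidationError(f"unknown entity id {item_id!r}")

    def has_staged_changes(self) -> bool:
        return any(self._added[c] or self._updated[c] for c in _COLLECTIONS)

    def unknown_category(self, kind_id: str) -> str:
        cid = _unknown_category_id(kind_id)
        if cid not in self.categories():
            raise ValidationError(f"unknown kind {kind_id!r}")
        return cid

    # -- staged edits -----------------------------------------------------

    def _stage_add(self, coll: str, entity) -> None:
        view = self._view(coll)
        if entity.id in view:
            raise ConflictError(f"duplicate id {entity.id!r} in {coll}")
        self._added[coll][entity.id] = entity

    def _stage_update(self, coll: str, eid: str, **fields) -> None:
        if eid in self._added[coll]:
            self._added[coll][eid] = replace(self._added[coll][eid], **fields)
        elif eid in self._committed[coll]:
            self._updated[coll].setdefault(eid, {}).update(fields)
        else:
            raise ValidationError(f"unknown {coll} id {eid!r}")

    def add_images(self, items: Sequence[ImageItem]) -> "Project":
        """Stage new images; defaults: partition=unassigned, category=Unknown."""
        for item in items:
            item.validate()
            if item.category_id is None:
                item.category_id = self.unknown_category(item.kind_id)
            if item.category_id not in self.categories():
                raise ValidationError(
                    f"image {item.id!r}: unknown category {item.category_id!r}"
                )
            self._stage_add("images", item)
        return self

    def register_kind(self, name: str) -> Kind:
        """Stage a new object kind with its reserved Unknown category."""
        if not name:
            raise ValidationError("kind name must be nonempty")
        if name in self.kinds():
            raise ConflictError(f"kind {name!r} already exists")
        kind = Kind(id=name, name=name)
        unk = Category(
            id=_unknown_category_id(name),
            name=UNKNOWN_CATEGORY_NAME,
            color=(128, 128, 128),
            kind_id=name,
        )
        kind.category_ids.append(unk.id)
        self._stage_add("kinds", kind)
        self._stage_add("categories", unk)
        return kind

    def register_category(
        self, kind_id: str, name: str, color: tuple[int, int, int]
    ) -> Category:
        kinds = self.kinds()
        if kind_id not in kinds:
            raise ValidationError(f"unknown kind {kind_id!r}")
        cats = self.categories()
        for cid in kinds[kind_id].category_ids:
            if cats[cid].name == name:
                raise ConflictError(f"category {name!r} already exists in kind {kind_id!r}")
        cat = Category(
            id=f"{kind_id}::{name}", name=name, color=tuple(color), kind_id=kind_id
        )
        self._stage_add("categories", cat)
        new_ids = kinds[kind_id].category_ids + [cat.id]
        self._stage_update("kinds", kind_id, category_ids=new_ids)
        return cat

    def delete_category(self, category_id: str) -> None:
        cat = self.categories().get(category_id)
        if cat is None:
            raise ValidationError(f"unknown category {category_id!r}")
        if cat.name == UNKNOWN_CATEGORY_NAME:
            raise ValidationError("the reserved Unknown category cannot be deleted")
        raise NotImplementedError("only reserved-category protection is enforced")

    def delete_kind(self, kind_id: str) -> None:
        if kind_id == IMAGE_KIND:
            raise ValidationError('the built-in "Image" kind cannot be deleted')
        raise NotImplementedError("only built-in-kind protection is enforced")

    def add_annotations(self, items: Sequence[AnnotationObject]) -> "Project":
        images = self.images()
        for ann in items:
            if ann.image_id not in images:
                raise ValidationError(
                    f"annotation {ann.id!r}: unknown image {ann.image_id!r}"
                )
            if ann.kind_id not in self.kinds():
                raise ValidationError(
                    f"annotation {ann.id!r}: unknown kind {ann.kind_id!r}"
                )
            if ann.category_id is None:
                ann.category_id = self.unknown_category(ann.kind_id)
            if ann.category_id not in self.categories():
                raise ValidationError(
                    f"annotation {ann.id!r}: unknown category {ann.category_id!r}"
                )
            ann.validate(image_extent=images[ann.image_id].extent)
            self._stage_add("annotations", ann)
        return self

    def assign(
        self,
        item_ids: Iterable[str],
        category_id: Optional[str] = None,
        partition: Optional[Partition] = None,
    ) -> "Project":
        """Stage category and/or partition assignment for images or objects."""
        if category_id is not None and category_id not in self.categories():
            raise ValidationError(f"unknown category {category_id!r}")
        for eid in item_ids:
            coll = None
            for c in ("images", "annotations"):
                if eid in self._view(c):
                    coll = c
                    break
            if coll is None:
                raise ValidationError(f"unknown image/annotation id {eid!r}")
            fields = {}
            if category_id is not None:
                item = self._view(coll)[eid]
                cat = self.categories()[category_id]
                if cat.kind_id != item.kind_id:
                    raise ValidationError(
                        f"category {category_id!r} belongs to kind {cat.kind_id!r}, "
                        f"item {eid!r} is of kind {item.kind_id!r}"
                    )
                fields["category_id"] = category_id
            if partition is not None:
                fields["partition"] = Partition(partition)
            if fields:
                self._stage_update(coll, eid, **fields)
        return self

    # -- split selection --------------------------------------------------

    def select_split(self, split: Split) -> list[str]:
        """Ids of items of the split's kind matching all filters, sorted by id."""
        kinds = self.kinds()
        if split.kind_id not in kinds:
            raise ValidationError(f"unknown kind {split.kind_id!r}")
        if split.category_ids:
            cats = self.categories()
            for cid in split.category_ids:
                if cid not in cats:
                    raise ValidationError(f"unknown category {cid!r}")
        pool = self.images() if split.kind_id == IMAGE_KIND else self.annotations()
        out = []
        for eid, item in pool.items():
            if item.kind_id != split.kind_id:
                continue
            if split.category_ids and item.category_id not in split.category_ids:
                continue
            if split.partitions and item.partition not in split.partitions:
                continue
            out.append(eid)
        return sorted(out)

    # -- commit / revert --------------------------------------------------

    def commit(self) -> "Project":
        """Fold staged changes into the committed state; clear the change set."""
        for coll in _COLLECTIONS:
            self._committed[coll].update(self._added[coll])
            for eid, diff in self._updated[coll].items():
                self._committed[coll][eid] = replace(self._committed[coll][eid], **diff)
            self._added[coll] = {}
            self._updated[coll] = {}
        return self

    def revert(self) -> "Project":
        """Discard the change set; the committed state is untouched."""
        for coll in _COLLECTIONS:
            self._added[coll] = {}
            self._updated[coll] = {}
        return self


def create_project(name: str) -> Project:
    """New project containing the built-in "Image" kind and its Unknown category."""
    return Project(name)
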