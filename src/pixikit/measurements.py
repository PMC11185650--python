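"""Per-image/per-object intensity and geometry measurements, split summaries,
and plot-ready series.

Intensity statistics are computed per channel over the pixels of an image, or
over the pixels under an object's mask on its annotation z-plane.  Geometry is
defined for objects only (it needs a mask) and is pixel-based:

* area            — number of foreground pixels
* perimeter       — number of foreground pixels with at least one background
                    (or out-of-extent) 4-neighbor (inner boundary count)
* bbox_area       — width x height of the tight bounding box
* extent          — area / bbox_area
* equivalent_diameter — diameter of the circle with the object's area,
                    2*sqrt(area/pi)
* ped             — diameter of the circle with the object's perimeter,
                    perimeter/pi
* sphericity      — perimeter of the equal-area circle over the object's
                    perimeter, 2*sqrt(pi*area)/perimeter; 1 for a circle
* compactness     — inverse of sphericity; > 1 for irregular shapes

Quartiles use a nearest-rank convention: the lower (upper) quartile is the
sorted value at 1-based rank floor(0.25*n)+1 (floor(0.75*n)+1), i.e. the
smallest pixel value such that 25% (75%) of the pixels have strictly lower
values whenever that fraction is attainable.  The MAD is the median of
absolute deviations from the median.  Standard deviations are population
(divide by n).

Results are cached per item and recomputed only when the underlying pixel or
mask buffer changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotator import annotation_to_full_mask
from .errors import ValidationError
from .project import IMAGE_KIND, AnnotationObject, ImageItem, Project, Split

GEOMETRY_MEASUREMENTS = (
    "area",
    "perimeter",
    "bbox_area",
    "extent",
    "equivalent_diameter",
    "ped",
    "sphericity",
    "compactness",
)
INTENSITY_MEASUREMENTS = (
    "intensity_total",
    "intensity_mean",
    "intensity_median",
    "intensity_std",
    "intensity_mad",
    "intensity_lower_quartile",
    "intensity_upper_quartile",
)
ALL_MEASUREMENTS = GEOMETRY_MEASUREMENTS + INTENSITY_MEASUREMENTS


# --------------------------------------------------------------------------
# intensity


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Sorted value at 1-based rank floor(q*n)+1 (clipped to n)."""
    v = np.sort(np.asarray(values).ravel())
    n = v.size
    rank = min(int(math.floor(q * n)) + 1, n)
    return float(v[rank - 1])


@dataclass(frozen=True)
class ChannelIntensity:
    total: float
    mean: float
    median: float
    std: float
    mad: float
    lower_quartile: float
    upper_quartile: float

    def as_dict(self) -> dict[str, float]:
        return {
            "intensity_total": self.total,
            "intensity_mean": self.mean,
            "intensity_median": self.median,
            "intensity_std": self.std,
            "intensity_mad": self.mad,
            "intensity_lower_quartile": self.lower_quartile,
            "intensity_upper_quartile": self.upper_quartile,
        }


@dataclass(frozen=True)
class IntensityStats:
    channels: tuple[ChannelIntensity, ...]


def _channel_intensity(values: np.ndarray) -> ChannelIntensity:
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValidationError("intensity statistics need at least one pixel")
    med = float(np.median(v))
    return ChannelIntensity(
        total=float(v.sum()),
        mean=float(v.mean()),
        median=med,
        std=float(v.std()),  # population
        mad=float(np.median(np.abs(v - med))),
        lower_quartile=nearest_rank_quantile(v, 0.25),
        upper_quartile=nearest_rank_quantile(v, 0.75),
    )


def intensity_stats(per_channel_values: Sequence[Sequence[float]]) -> IntensityStats:
    """Seven intensity statistics for each channel's pixel values."""
    return IntensityStats(tuple(_channel_intensity(ch) for ch in per_channel_values))


# --------------------------------------------------------------------------
# geometry


def primitive_geometry(mask: np.ndarray) -> tuple[int, int, int]:
    """(area, perimeter, bbox_area) of a nonempty binary mask.

    Perimeter counts foreground pixels with >= 1 background or out-of-extent
    4-neighbor; bbox is the tight box around the foreground.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValidationError("empty mask")
    area = int(m.sum())
    padded = np.pad(m, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    perimeter = int((m & ~interior).sum())
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    bbox_area = int((rows[-1] - rows[0] + 1) * (cols[-1] - cols[0] + 1))
    return area, perimeter, bbox_area


@dataclass(frozen=True)
class GeometryRecord:
    area: float
    perimeter: float
    bbox_area: float
    extent: float
    equivalent_diameter: float
    ped: float
    sphericity: float
    compactness: float

    def as_dict(self) -> dict[str, float]:
        return {
            "area": self.area,
            "perimeter": self.perimeter,
            "bbox_area": self.bbox_area,
            "extent": self.extent,
            "equivalent_diameter": self.equivalent_diameter,
            "ped": self.ped,
            "sphericity": self.sphericity,
            "compactness": self.compactness,
        }


def derived_geometry(area: float, perimeter: float, bbox_area: float) -> GeometryRecord:
    """Derived shape descriptors from (possibly analytic, non-integer) primitives."""
    if area <= 0 or perimeter <= 0:
        raise ValidationError("area and perimeter must be positive")
    if bbox_area < area:
        raise ValidationError("bbox_area must be >= area")
    sphericity = 2.0 * math.sqrt(math.pi * area) / perimeter
    return GeometryRecord(
        area=float(area),
        perimeter=float(perimeter),
        bbox_area=float(bbox_area),
        extent=float(area / bbox_area),
        equivalent_diameter=2.0 * math.sqrt(area / math.pi),
        ped=float(perimeter / math.pi),
        sphericity=sphericity,
        compactness=1.0 / sphericity,
    )


def mask_geometry(mask: np.ndarray) -> GeometryRecord:
    """Pixel-based geometry of a binary mask (primitives + derived)."""
    return derived_geometry(*primitive_geometry(mask))


# --------------------------------------------------------------------------
# split measurement


@dataclass
class MeasurementTable:
    """Long-form rows (item, measurement, channel) plus split summaries."""

    split: Split
    rows: pd.DataFrame  # item_id, kind, category, partition, measurement, channel, value
    summaries: pd.DataFrame  # measurement, channel, total, median, std

    def values(self, measurement: str, channel: Optional[int] = None) -> pd.Series:
        sel = self.rows[self.rows["measurement"] == measurement]
        if channel is not None:
            sel = sel[sel["channel"] == channel]
        return sel.set_index("item_id")["value"]


def _object_pixels(project: Project, ann: AnnotationObject) -> np.ndarray:
    """(channel, n_pixels) intensities under the mask on the annotation plane."""
    image: ImageItem = project.images()[ann.image_id]
    plane = image.pixels[ann.z_index]  # (c, y, x)
    full = annotation_to_full_mask(ann, image.extent)
    return plane[:, full]


def _cache(project: Project) -> dict:
    return project.__dict__.setdefault("_measurement_cache", {})


def _measure_item(project: Project, item_id: str, measurements: Sequence[str]):
    """Rows [(measurement, channel, value)] for one item, cached per data buffer."""
    item = project.get(item_id)
    is_image = isinstance(item, ImageItem)
    if is_image:
        token = item.data_token
    else:
        token = (item.data_token, project.images()[item.image_id].data_token)
    cache = _cache(project)
    key = (item_id, tuple(measurements))
    hit = cache.get(key)
    if hit is not None and hit[0] == token:
        return hit[1]

    rows: list[tuple[str, int, float]] = []
    geo_wanted = [m for m in measurements if m in GEOMETRY_MEASUREMENTS]
    int_wanted = [m for m in measurements if m in INTENSITY_MEASUREMENTS]
    if geo_wanted:
        geo = mask_geometry(item.mask).as_dict()
        rows.extend((m, 0, geo[m]) for m in geo_wanted)
    if int_wanted:
        if is_image:
            per_channel = [
                item.pixels[:, ch].ravel() for ch in range(item.pixels.shape[1])
            ]
        else:
            vals = _object_pixels(project, item)
            per_channel = [vals[ch] for ch in range(vals.shape[0])]
        stats = intensity_stats(per_channel)
        for ch, cs in enumerate(stats.channels):
            d = cs.as_dict()
            rows.extend((m, ch, d[m]) for m in int_wanted)
    cache[key] = (token, rows)
    return rows


def measure_split(
    project: Project, split: Split, measurements: Sequence[str]
) -> MeasurementTable:
    """Measure every item of a split; summarize each measurement per channel.

    Geometry measurements are rejected for the "Image" kind: geometry needs an
    object mask, which plain images do not have.
    """
    for m in measurements:
        if m not in ALL_MEASUREMENTS:
            raise ValidationError(f"unknown measurement {m!r}")
    if split.kind_id == IMAGE_KIND and any(
        m in GEOMETRY_MEASUREMENTS for m in measurements
    ):
        raise ValidationError(
            'geometry measurements require an object mask and cannot be computed '
            'for the "Image" kind'
        )
    item_ids = project.select_split(split)
    records = []
    for item_id in item_ids:
        item = project.get(item_id)
        for m, ch, value in _measure_item(project, item_id, measurements):
            records.append(
                {
                    "item_id": item_id,
                    "kind": item.kind_id,
                    "category": item.category_id,
                    "partition": item.partition.value,
                    "measurement": m,
                    "channel": ch,
                    "value": value,
                }
            )
    columns = ["item_id", "kind", "category", "partition", "measurement", "channel", "value"]
    rows = pd.DataFrame.from_records(records, columns=columns)
    if rows.empty:
        summaries = pd.DataFrame(columns=["measurement", "channel", "total", "median", "std"])
    else:
        summaries = (
            rows.groupby(["measurement", "channel"])["value"]
            .agg(total="sum", median="median", std=lambda v: float(np.std(v)))
            .reset_index()
        )
    return MeasurementTable(split=split, rows=rows, summaries=summaries)


# --------------------------------------------------------------------------
# plot-ready series


def plot_series(table: MeasurementTable, plot_kind: str, **params) -> dict:
    """Numeric series for a histogram, scatter, or swarm plot (no rendering).

    histogram: x (measurement), bins (count), optional channel.
    scatter:   x, y (measurements), optional size measurement, optional
               color_by ("category" | "partition"), optional channel.
    swarm:     y (measurement), group_by ("category" | "partition"),
               optional size, optional overlay (bool), optional channel.
    """
    if plot_kind == "histogram":
        x = params["x"]
        bins = int(params.get("bins", 10))
        if bins < 1:
            raise ValidationError("bin count must be >= 1")
        values = table.values(x, params.get("channel")).to_numpy()
        counts, edges = np.histogram(values, bins=bins)
        return {"bin_edges": edges, "counts": counts}

    if plot_kind == "scatter":
        ch = params.get("channel")
        xs = table.values(params["x"], ch)
        ys = table.values(params["y"], ch)
        joined = pd.DataFrame({"x": xs, "y": ys}).dropna()
        out = {
            "item_id": joined.index.to_numpy(),
            "x": joined["x"].to_numpy(),
            "y": joined["y"].to_numpy(),
        }
        if "size" in params and params["size"]:
            out["size"] = table.values(params["size"], ch).reindex(joined.index).to_numpy()
        if params.get("color_by"):
            meta = table.rows.drop_duplicates("item_id").set_index("item_id")
            out["color_group"] = meta[params["color_by"]].reindex(joined.index).to_numpy()
        return out

    if plot_kind == "swarm":
        y = params["y"]
        group_by = params.get("group_by", "category")
        ch = params.get("channel")
        sel = table.rows[table.rows["measurement"] == y]
        if ch is not None:
            sel = sel[sel["channel"] == ch]
        groups: dict[str, np.ndarray] = {
            str(g): sub["value"].to_numpy() for g, sub in sel.groupby(group_by)
        }
        out: dict = {"groups": groups}
        if params.get("overlay"):
            overlay = {}
            for g, v in groups.items():
                overlay[g] = {
                    "median": float(np.median(v)),
                    "std": float(np.std(v)),
                    "lower_quartile": nearest_rank_quantile(v, 0.25),
                    "upper_quartile": nearest_rank_quantile(v, 0.75),
                }
            out["overlay"] = overlay
        return out

    raise ValidationError(f"unknown plot kind {plot_kind!r}")
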