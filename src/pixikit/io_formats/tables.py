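"""Deterministic CSV export of measurement tables.

One row per (item, channel); columns are item id, kind, category, partition,
channel, then the measurement columns in their canonical order.  Geometry
values (channel-independent) are repeated on each channel row.  Floats are
serialized with 6 significant digits, so re-exporting an unchanged table is
byte-identical.
"""

from __future__ import annotations

import csv

from ..errors import ValidationError
from ..measurements import ALL_MEASUREMENTS, MeasurementTable


def _fmt(value) -> str:
    if value is None or value != value:  # NaN
        return ""
    return format(float(value), ".6g")


def export_measurements_csv(table: MeasurementTable, path) -> None:
    rows = table.rows
    if rows.empty:
        raise ValidationError("measurement table is empty")
    measurements = [m for m in ALL_MEASUREMENTS if m in set(rows["measurement"])]
    meta = rows.drop_duplicates("item_id").set_index("item_id")

    wide: dict[tuple[str, int], dict[str, float]] = {}
    for rec in rows.itertuples():
        wide.setdefault((rec.item_id, rec.channel), {})[rec.measurement] = rec.value
    # geometry rows land on channel 0; copy them across each channel of the item
    items_channels: dict[str, set[int]] = {}
    for item_id, ch in wide:
        items_channels.setdefault(item_id, set()).add(ch)
    for item_id, chans in items_channels.items():
        base = wide.get((item_id, 0), {})
        for ch in chans:
            for m in measurements:
                if m not in wide[(item_id, ch)] and m in base:
                    wide[(item_id, ch)][m] = base[m]

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["item_id", "kind", "category", "partition", "channel", *measurements])
        for (item_id, ch) in sorted(wide):
            info = meta.loc[item_id]
            writer.writerow(
                [item_id, info["kind"], info["category"], info["partition"], ch]
                + [_fmt(wide[(item_id, ch)].get(m)) for m in measurements]
            )
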