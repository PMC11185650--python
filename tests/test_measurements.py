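"""Measurement formulas against brute-force oracles and closed forms."""

import math

import numpy as np
import pytest

from pixikit.errors import ValidationError
from pixikit.fixtures import plus_sign_mask
from pixikit.measurements import (
    ALL_MEASUREMENTS,
    GEOMETRY_MEASUREMENTS,
    derived_geometry,
    intensity_stats,
    measure_split,
    nearest_rank_quantile,
    plot_series,
    primitive_geometry,
)
from pixikit.project import IMAGE_KIND, Split

from conftest import random_mask


# -- independent oracles ----------------------------------------------------


def geometry_oracle(mask: np.ndarray) -> tuple[int, int, int]:
    """Naive double-loop area/boundary/bbox computation."""
    h, w = mask.shape
    area = perimeter = 0
    rmin, rmax, cmin, cmax = h, -1, w, -1
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            area += 1
            rmin, rmax = min(rmin, r), max(rmax, r)
            cmin, cmax = min(cmin, c), max(cmax, c)
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                    perimeter += 1
                    break
    return area, perimeter, (rmax - rmin + 1) * (cmax - cmin + 1)


def intensity_oracle(values) -> dict:
    """Sort-based evaluation of the stated statistic definitions."""
    v = sorted(float(x) for x in values)
    n = len(v)
    med = (v[(n - 1) // 2] + v[n // 2]) / 2
    devs = sorted(abs(x - med) for x in v)
    mad = (devs[(n - 1) // 2] + devs[n // 2]) / 2
    mean = sum(v) / n
    return {
        "total": sum(v),
        "mean": mean,
        "median": med,
        "std": math.sqrt(sum((x - mean) ** 2 for x in v) / n),
        "mad": mad,
        "lower_quartile": v[min(n // 4, n - 1)],
        "upper_quartile": v[min((3 * n) // 4, n - 1)],
    }


# -- intensity --------------------------------------------------------------


class TestIntensityStats:
    def test_mad_is_median_of_absolute_deviations(self):
        ch = intensity_stats([[1, 2, 3, 4, 100]]).channels[0]
        assert ch.median == 3 and ch.mad == 1

    def test_constant_values(self):
        ch = intensity_stats([[0.4] * 7]).channels[0]
        assert ch.total == pytest.approx(2.8)
        assert ch.std == pytest.approx(0, abs=1e-12) and ch.mad == 0
        assert ch.lower_quartile == ch.median == ch.upper_quartile == 0.4

    def test_quartile_has_stated_fraction_strictly_lower(self):
        values = np.arange(1, 101)
        lq = nearest_rank_quantile(values, 0.25)
        uq = nearest_rank_quantile(values, 0.75)
        assert (values < lq).mean() == 0.25
        assert (values < uq).mean() == 0.75

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_sort_based_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.random(int(rng.integers(1, 200)))
        ch = intensity_stats([values]).channels[0]
        expected = intensity_oracle(values)
        for field, want in expected.items():
            assert getattr(ch, field) == pytest.approx(want, abs=1e-12), field

    def test_empty_channel_rejected(self):
        with pytest.raises(ValidationError):
            intensity_stats([[]])


# -- geometry ---------------------------------------------------------------


class TestPrimitiveGeometry:
    @pytest.mark.parametrize(
        "builder,expected",
        [
            (lambda: np.ones((1, 1), bool), (1, 1, 1)),
            (lambda: np.ones((4, 4), bool), (16, 12, 16)),
            (lambda: plus_sign_mask(), (45, 28, 81)),
        ],
        ids=["single-pixel", "solid-square", "plus-sign"],
    )
    def test_known_shapes(self, builder, expected):
        mask = builder()
        assert primitive_geometry(mask) == expected
        assert geometry_oracle(mask) == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = random_mask(rng, max_side=32)
        assert primitive_geometry(mask) == geometry_oracle(mask)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            primitive_geometry(np.zeros((3, 3), bool))


class TestDerivedGeometry:
    def test_analytic_circle_is_the_symmetry_point(self):
        # r=2 circle: area 4*pi, perimeter 4*pi, bbox 4x4
        g = derived_geometry(4 * math.pi, 4 * math.pi, 16.0)
        assert g.sphericity == pytest.approx(1.0, abs=1e-15)
        assert g.compactness == pytest.approx(1.0, abs=1e-15)
        assert g.equivalent_diameter == pytest.approx(4.0)
        assert g.ped == pytest.approx(4.0)
        assert g.extent == pytest.approx(math.pi / 4)

    def test_printed_formula_evaluation(self):
        g = derived_geometry(100.0, 40.0, 100.0)
        assert g.extent == 1.0
        assert g.equivalent_diameter == pytest.approx(11.2838, abs=1e-4)
        assert g.ped == pytest.approx(12.7324, abs=1e-4)
        assert g.sphericity == pytest.approx(0.8862, abs=1e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_compactness_is_inverse_sphericity(self, seed):
        rng = np.random.default_rng(seed)
        area = rng.uniform(1, 500)
        perim = rng.uniform(1, 200)
        g = derived_geometry(area, perim, area * rng.uniform(1, 3))
        assert g.compactness * g.sphericity == pytest.approx(1.0, rel=1e-14)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            derived_geometry(0, 10, 10)
        with pytest.raises(ValidationError):
            derived_geometry(10, 10, 5)


# -- split measurement ------------------------------------------------------


class TestMeasureSplit:
    def test_summary_total_and_median_of_areas(self, scene_project):
        table = measure_split(scene_project, Split(kind_id="object"), ["area"])
        areas = sorted(table.values("area"))
        expected_total = sum(areas)
        summary = table.summaries.set_index("measurement").loc["area"]
        assert summary["total"] == expected_total
        assert summary["median"] == areas[1]
        # plus-sign fixture is present with area 45
        assert 45 in areas

    def test_empty_split_gives_empty_table(self, scene_project):
        table = measure_split(
            scene_project,
            Split(kind_id="object", partitions={"inference"}),
            ["area"],
        )
        assert table.rows.empty

    def test_geometry_on_image_kind_rejected(self, scene_project):
        with pytest.raises(ValidationError):
            measure_split(scene_project, Split(kind_id=IMAGE_KIND), ["area"])

    def test_image_intensity_allowed_and_per_channel(self, scene_project):
        table = measure_split(
            scene_project, Split(kind_id=IMAGE_KIND), ["intensity_mean"]
        )
        assert len(table.rows) == 1  # one image, one channel
        img = scene_project.images()["img1"]
        assert table.rows["value"].iloc[0] == pytest.approx(img.pixels.mean())

    def test_object_intensity_uses_only_mask_pixels(self, scene_project):
        ids = scene_project.select_split(Split(kind_id="object"))
        table = measure_split(
            scene_project, Split(kind_id="object"), ["intensity_mean"]
        )
        # noise-free scene: every object pixel has the object intensity 0.8
        assert np.allclose(table.values("intensity_mean"), 0.8)
        assert len(table.rows) == len(ids)

    def test_summaries_permutation_invariant(self, scene_project):
        t1 = measure_split(scene_project, Split(kind_id="object"), ["area", "perimeter"])
        t2 = measure_split(scene_project, Split(kind_id="object"), ["perimeter", "area"])
        s1 = t1.summaries.sort_values("measurement").reset_index(drop=True)
        s2 = t2.summaries.sort_values("measurement").reset_index(drop=True)
        assert s1.equals(s2)

    def test_results_cached_until_data_changes(self, scene_project):
        measure_split(scene_project, Split(kind_id="object"), ["area"])
        cache = scene_project.__dict__["_measurement_cache"]
        tokens = {k: id(v[1]) for k, v in cache.items()}
        measure_split(scene_project, Split(kind_id="object"), ["area"])
        cache2 = scene_project.__dict__["_measurement_cache"]
        assert {k: id(v[1]) for k, v in cache2.items()} == tokens

    def test_unknown_measurement_rejected(self, scene_project):
        with pytest.raises(ValidationError):
            measure_split(scene_project, Split(kind_id="object"), ["fractal_dim"])


# -- plot series ------------------------------------------------------------


class TestPlotSeries:
    def test_histogram_half_open_bins_last_closed(self, scene_project):
        table = measure_split(scene_project, Split(kind_id="object"), ["area"])
        out = plot_series(table, "histogram", x="area", bins=2)
        assert out["counts"].sum() == 3
        # areas {45, 60, 112}: bins [45, 78.5) and [78.5, 112] -> [2, 1]
        assert list(out["counts"]) == [2, 1]

    def test_histogram_bad_bin_count(self, scene_project):
        table = measure_split(scene_project, Split(kind_id="object"), ["area"])
        with pytest.raises(ValidationError):
            plot_series(table, "histogram", x="area", bins=0)

    def test_swarm_overlay_statistics_convention(self, scene_project):
        import pandas as pd

        from pixikit.measurements import MeasurementTable

        rows = pd.DataFrame(
            {
                "item_id": [f"i{k}" for k in range(100)],
                "kind": "object",
                "category": "c",
                "partition": "train",
                "measurement": "area",
                "channel": 0,
                "value": np.arange(1, 101, dtype=float),
            }
        )
        table = MeasurementTable(split=Split(kind_id="object"), rows=rows,
                                 summaries=pd.DataFrame())
        out = plot_series(table, "swarm", y="area", group_by="category", overlay=True)
        stats = out["overlay"]["c"]
        assert stats["median"] == 50.5
        assert stats["lower_quartile"] == nearest_rank_quantile(np.arange(1, 101), 0.25)
        assert stats["upper_quartile"] == nearest_rank_quantile(np.arange(1, 101), 0.75)

    def test_scatter_cardinality_and_monotone_sizes(self, scene_project):
        table = measure_split(
            scene_project, Split(kind_id="object"), ["area", "perimeter", "bbox_area"]
        )
        out = plot_series(table, "scatter", x="area", y="perimeter", size="bbox_area")
        assert len(out["x"]) == 3
        order_by_size = np.argsort(out["size"])
        bbox = table.values("bbox_area").loc[out["item_id"]].to_numpy()
        assert (np.argsort(bbox) == order_by_size).all()

    def test_unknown_plot_kind(self, scene_project):
        table = measure_split(scene_project, Split(kind_id="object"), ["area"])
        with pytest.raises(ValidationError):
            plot_series(table, "violin", y="area")
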