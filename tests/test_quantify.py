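import numpy as np
import pytest

from histoquant.errors import (
    AggregationError,
    GeometryError,
    ParameterError,
    SpecError,
)
from histoquant.objects import SegmentationMask, object_stats
from histoquant.quantify import (
    CustomRegionSpec,
    RegionReport,
    aggregate_series,
    apply_custom_regions,
    assign_object_region,
    build_region_reports,
    load_custom_regions,
    pixelwise_region_areas,
    point_grid_area_fraction,
    region_pixel_areas,
    section_pixel_fraction,
    whole_section_summary,
)
from histoquant.transform import ScaleSpec

from .conftest import make_map

SCALE = ScaleSpec(1.0, 1.0)


def report(region_id, name, region_area_px, object_count, object_area_px):
    load = object_area_px / region_area_px if region_area_px else None
    return RegionReport(
        region_id=region_id, name=name, acronym=name,
        region_area_px=region_area_px, region_area_um2=float(region_area_px),
        object_count=object_count,
        object_area_px=object_area_px, object_area_um2=float(object_area_px),
        load=load,
    )


class TestRegionPixelAreas:
    def test_all_background(self):
        assert region_pixel_areas(make_map(np.zeros((4, 4), int))) == {0: 16}

    def test_mixed(self):
        assert region_pixel_areas(make_map([[1, 1], [2, 0]])) == {1: 2, 2: 1, 0: 1}

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(5)
        labels = rng.choice([0, 1, 2, 3, 5], size=(16, 16))
        got = region_pixel_areas(make_map(labels))
        expected: dict[int, int] = {}
        for y in range(16):
            for x in range(16):
                expected[int(labels[y, x])] = expected.get(int(labels[y, x]), 0) + 1
        assert got == expected
        assert sum(got.values()) == 16 * 16


class TestAssignObjectRegion:
    def test_inside_one_region(self):
        amap = make_map(np.full((5, 5), 5, int))
        obj = object_stats([(2, 2), (3, 2)])
        assert assign_object_region(obj, amap) == 5

    def test_top_left_rule_beats_majority(self):
        # anchor in region 5, 9 of 10 pixels in region 6: anchor wins
        labels = np.full((4, 10), 6, int)
        labels[0, 0] = 5
        amap = make_map(labels)
        pixels = [(0, 0)] + [(x, 1) for x in range(9)]
        obj = object_stats(pixels)
        assert obj.anchor_pixel == (0, 0)
        assert assign_object_region(obj, amap) == 5

    def test_out_of_bounds_anchor(self):
        amap = make_map(np.zeros((4, 8), int))
        obj = object_stats([(10, 0)])
        with pytest.raises(GeometryError):
            assign_object_region(obj, amap)


class TestPixelwiseRegionAreas:
    def test_even_straddle(self):
        labels = np.zeros((2, 4), int)
        labels[:, :2] = 1
        labels[:, 2:] = 2
        obj = object_stats([(1, 0), (2, 0), (1, 1), (2, 1)])
        assert pixelwise_region_areas([obj], make_map(labels)) == {1: 2, 2: 2}

    def test_no_objects(self):
        assert pixelwise_region_areas([], make_map(np.zeros((2, 2), int))) == {}

    def test_matches_per_pixel_lookup_oracle(self):
        rng = np.random.default_rng(9)
        labels = rng.choice([0, 1, 2, 3], size=(20, 20))
        pixels = {(int(x), int(y)) for x, y in rng.integers(0, 20, (60, 2))}
        objs = [object_stats(sorted(pixels))]
        got = pixelwise_region_areas(objs, make_map(labels))
        expected: dict[int, int] = {}
        for x, y in pixels:
            rid = int(labels[y, x])
            expected[rid] = expected.get(rid, 0) + 1
        assert got == expected


class TestBuildRegionReports:
    def test_single_object_load(self, table):
        amap = make_map(np.full((10, 10), 1, int))
        obj = object_stats([(i, 0) for i in range(7)], object_id=1)
        (rep,) = build_region_reports([obj], amap, table, SCALE)
        assert rep.region_id == 1
        assert rep.object_count == 1
        assert rep.object_area_px == 7
        assert rep.region_area_px == 100
        assert rep.load == pytest.approx(0.07)

    def test_no_objects_zero_loads(self, table):
        labels = np.zeros((4, 4), int)
        labels[:2] = 1
        reports = build_region_reports([], make_map(labels), table, SCALE)
        assert all(r.object_count == 0 and r.load == 0.0 for r in reports)

    def test_conservation_pixel_attribution(self, table):
        rng = np.random.default_rng(2)
        labels = rng.choice([0, 1, 2, 3], size=(16, 16))
        pixels = sorted({(int(x), int(y)) for x, y in rng.integers(0, 16, (40, 2))})
        objs = [object_stats(pixels, object_id=1)]
        reports = build_region_reports(objs, make_map(labels), table, SCALE)
        assert sum(r.object_area_px for r in reports) == len(pixels)
        assert sum(r.region_area_px for r in reports) == 16 * 16

    def test_attribution_modes_agree_when_no_straddling(self, table):
        labels = np.zeros((8, 8), int)
        labels[:, :4] = 1
        labels[:, 4:] = 2
        objs = [
            object_stats([(0, 0), (1, 0)], object_id=1),
            object_stats([(5, 5), (5, 6)], object_id=2),
        ]
        amap = make_map(labels)
        for_pixel = build_region_reports(objs, amap, table, SCALE, attribution="pixel")
        for_anchor = build_region_reports(objs, amap, table, SCALE, attribution="anchor")
        assert for_pixel == for_anchor

    def test_whole_section_summary_is_pooled_ratio(self, table):
        labels = np.zeros((10, 10), int)
        labels[:5] = 1
        labels[5:] = 2
        objs = [
            object_stats([(x, 0) for x in range(4)], object_id=1),
            object_stats([(x, 7) for x in range(6)], object_id=2),
        ]
        reports = build_region_reports(objs, make_map(labels), table, SCALE)
        summary = whole_section_summary(reports, SCALE, exclude_ids=(0,))
        assert summary.region_id == -1
        assert summary.object_area_px == 10
        assert summary.region_area_px == 100
        assert summary.load == pytest.approx(10 / 100)

    def test_zero_area_region_flagged_not_nan(self, table):
        amap = make_map(np.full((2, 2), 1, int))
        reports = build_region_reports([], amap, table, SCALE, include_zero_area=True)
        by_id = {r.region_id: r for r in reports}
        assert by_id[2].region_area_px == 0
        assert by_id[2].load is None
        assert not by_id[2].load_defined


class TestCustomRegions:
    def test_merge_is_area_weighted(self, table):
        reports = [report(1, "A", 100, 1, 10), report(2, "B", 300, 1, 3)]
        spec = CustomRegionSpec(groups=(("AB", (1, 2)),))
        (merged,) = apply_custom_regions(reports, spec, table, SCALE)
        assert merged.name == "AB"
        assert merged.region_area_px == 400
        assert merged.object_area_px == 13
        assert merged.load == pytest.approx(13 / 400)  # not mean(0.10, 0.01)

    def test_empty_spec_unchanged(self, table):
        reports = [report(1, "A", 10, 0, 0)]
        assert apply_custom_regions(reports, CustomRegionSpec(), table, SCALE) == reports

    def test_unknown_id(self, table):
        spec = CustomRegionSpec(groups=(("G", (999,)),))
        with pytest.raises(SpecError):
            apply_custom_regions([], spec, table, SCALE)

    def test_exclusion_removes_region(self, table):
        reports = [report(1, "A", 10, 1, 1), report(2, "B", 10, 1, 1)]
        spec = CustomRegionSpec(excluded=(2,))
        out = apply_custom_regions(reports, spec, table, SCALE)
        assert [r.region_id for r in out] == [1]

    def test_overlapping_groups_rejected(self):
        with pytest.raises(SpecError):
            CustomRegionSpec(groups=(("A", (1, 2)), ("B", (2, 3))))

    def test_merged_load_equals_merged_mask_recompute(self, table):
        # merging regions 1 and 2 must equal the load computed on a map where
        # both carry a single label
        rng = np.random.default_rng(4)
        labels = rng.choice([1, 2, 3], size=(12, 12))
        pixels = sorted({(int(x), int(y)) for x, y in rng.integers(0, 12, (30, 2))})
        objs = [object_stats(pixels, object_id=1)]
        reports = build_region_reports(objs, make_map(labels), table, SCALE)
        spec = CustomRegionSpec(groups=(("merged", (1, 2)),))
        merged = apply_custom_regions(reports, spec, table, SCALE)[0]
        relabelled = np.where(labels == 2, 1, labels)
        rereports = build_region_reports(objs, make_map(relabelled), table, SCALE)
        ref = next(r for r in rereports if r.region_id == 1)
        assert merged.region_area_px == ref.region_area_px
        assert merged.object_area_px == ref.object_area_px
        assert merged.load == pytest.approx(ref.load)

    def test_load_from_csv_with_descendants(self, tmp_path):
        from histoquant.atlas_io import LabelTable, RegionRecord

        table = LabelTable(
            [
                RegionRecord(0, "bg", "bg", (0, 0, 0), None),
                RegionRecord(1, "top", "t", (1, 0, 0), None),
                RegionRecord(2, "kid", "k", (2, 0, 0), 1),
                RegionRecord(3, "grandkid", "g", (3, 0, 0), 2),
                RegionRecord(4, "other", "o", (4, 0, 0), None),
            ]
        )
        path = tmp_path / "custom.csv"
        path.write_text(
            "group_name,member_ids\nfamily,1+\nEXCLUDE,4\n", encoding="utf-8"
        )
        spec = load_custom_regions(path, table)
        assert spec.groups == (("family", (1, 2, 3)),)
        assert spec.excluded == (4,)


class TestAggregateSeries:
    def test_equal_area_sections(self):
        sec = [report(1, "A", 100, 1, 10)]
        out = aggregate_series([sec, sec], SCALE)
        assert out[0].region_area_px == 200
        assert out[0].object_area_px == 20
        assert out[0].load == pytest.approx(0.1)

    def test_region_in_one_section_only(self):
        s1 = [report(1, "A", 100, 1, 10)]
        s2 = [report(2, "B", 50, 1, 5)]
        out = aggregate_series([s1, s2], SCALE)
        by_id = {r.region_id: r for r in out}
        assert by_id[2].region_area_px == 50  # that section's area only
        assert by_id[2].load == pytest.approx(0.1)

    def test_inconsistent_identity(self):
        s1 = [report(1, "A", 10, 0, 0)]
        s2 = [report(1, "Avenue", 10, 0, 0)]
        with pytest.raises(AggregationError):
            aggregate_series([s1, s2], SCALE)

    def test_matches_pooled_recompute_oracle(self, table):
        rng = np.random.default_rng(17)
        sections = []
        pooled_area: dict[int, int] = {}
        pooled_obj: dict[int, int] = {}
        for _ in range(5):
            labels = rng.choice([0, 1, 2, 3], size=(10, 10))
            pixels = sorted({(int(x), int(y)) for x, y in rng.integers(0, 10, (15, 2))})
            objs = [object_stats(pixels, object_id=1)]
            reports = build_region_reports(objs, make_map(labels), table, SCALE)
            sections.append(reports)
            for r in reports:
                pooled_area[r.region_id] = pooled_area.get(r.region_id, 0) + r.region_area_px
                pooled_obj[r.region_id] = pooled_obj.get(r.region_id, 0) + r.object_area_px
        out = aggregate_series(sections, SCALE)
        for r in out:
            assert r.region_area_px == pooled_area[r.region_id]
            assert r.object_area_px == pooled_obj[r.region_id]
            assert r.load == pytest.approx(pooled_obj[r.region_id] / pooled_area[r.region_id])


class TestPointGrid:
    def _mask(self, member):
        return SegmentationMask(np.asarray(member, bool), (255, 0, 255))

    def test_all_labelled(self):
        est = point_grid_area_fraction(self._mask(np.ones((700, 700))), SCALE)
        assert est.fraction == 1.0
        assert est.total_points > 0

    def test_all_background(self):
        est = point_grid_area_fraction(self._mask(np.zeros((700, 700))), SCALE)
        assert est.fraction == 0.0

    def test_random_half_mask_within_three_se(self):
        # exactly half the pixels are members, in random (aperiodic)
        # positions, so grid points behave like Bernoulli(0.5) draws
        rng = np.random.default_rng(31)
        member = np.zeros(600 * 600, bool)
        member[rng.permutation(member.size)[: member.size // 2]] = True
        mask = self._mask(member.reshape(600, 600))
        assert section_pixel_fraction(mask) == 0.5
        est = point_grid_area_fraction(mask, SCALE, point_spacing_um=5.0)
        se = (0.25 / est.total_points) ** 0.5
        assert abs(est.fraction - 0.5) <= 3 * se

    def test_refinement_converges_to_pixel_fraction(self):
        member = np.zeros((600, 600), bool)
        member[:, :300] = True  # exactly half
        mask = self._mask(member)
        true = section_pixel_fraction(mask)
        errors = []
        for spacing in (40.0, 20.0, 10.0):
            est = point_grid_area_fraction(mask, SCALE, point_spacing_um=spacing)
            errors.append(abs(est.fraction - true))
        assert errors[0] >= errors[1] >= errors[2]
        assert errors[2] <= 1e-12

    def test_frame_larger_than_grid_rejected(self):
        with pytest.raises(ParameterError):
            point_grid_area_fraction(
                self._mask(np.ones((10, 10))), SCALE,
                grid_um=(100.0, 100.0), frame_um=(200.0, 200.0),
            )

    def test_single_pixel_receives_origin_point(self):
        # the frame origin always contributes the (0, 0) test point
        est = point_grid_area_fraction(
            self._mask(np.ones((1, 1))), ScaleSpec(1.0, 1.0),
            grid_um=(300.0, 300.0), frame_um=(200.0, 200.0),
            point_spacing_um=20.0,
        )
        assert est.total_points == 1
        assert est.fraction == 1.0

    def test_counting_frame_restricts_points(self):
        # grid 300, frame 200, spacing 20 on a 600 um wide mask: 2 frames of
        # 10 points per axis = 20 positions per axis, 400 points total
        est = point_grid_area_fraction(self._mask(np.ones((600, 600))), SCALE)
        assert est.total_points == 400
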