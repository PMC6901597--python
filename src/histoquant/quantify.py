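"""Per-region quantification of extracted objects against an atlas map.

Two attribution rules coexist and are both exposed:

* **anchor** — a whole object is credited to the region under its top-left
  member pixel (the lookup rule used for object counts);
* **pixel** — each labelled pixel is credited to the region directly under
  it (the rule the load fraction is defined with).

Object *counts* always use the anchor rule; object *areas* use the chosen
attribution mode (default ``pixel``), so the discrepancy between the two
definitions is explicit rather than hidden.
"""

from __future__ import annotations

import csv
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .atlas_io import AtlasMap, LabelTable
from .errors import AggregationError, GeometryError, ParameterError, SpecError
from .objects import ExtractedObject, SegmentationMask
from .transform import ScaleSpec, pixel_area_um2

ATTRIBUTION_MODES = ("pixel", "anchor")

REPORT_COLUMNS = (
    "region_id", "name", "acronym", "region_area_px", "region_area_um2",
    "object_count", "object_area_px", "object_area_um2", "load",
)

#: region_id used for the whole-section/whole-series summary row in CSVs.
SUMMARY_REGION_ID = -1


@dataclass(frozen=True)
class RegionReport:
    """Counts, areas and load for one region (or merged group) of one scope.

    ``load`` is ``object_area_px / region_area_px``; it is ``None`` (flagged,
    not silently NaN) when the region has zero area.  ``region_id`` is
    ``None`` for merged custom groups, which are identified by name.
    """

    region_id: int | None
    name: str
    acronym: str
    region_area_px: int
    region_area_um2: float
    object_count: int
    object_area_px: int
    object_area_um2: float
    load: float | None

    @property
    def load_defined(self) -> bool:
        return self.load is not None


def _make_report(
    region_id: int | None,
    name: str,
    acronym: str,
    region_area_px: int,
    object_count: int,
    object_area_px: int,
    scale: ScaleSpec,
) -> RegionReport:
    px_area = pixel_area_um2(scale)
    load = (object_area_px / region_area_px) if region_area_px > 0 else None
    return RegionReport(
        region_id=region_id,
        name=name,
        acronym=acronym,
        region_area_px=region_area_px,
        region_area_um2=region_area_px * px_area,
        object_count=object_count,
        object_area_px=object_area_px,
        object_area_um2=object_area_px * px_area,
        load=load,
    )


def region_pixel_areas(amap: AtlasMap) -> dict[int, int]:
    """Pixel count of every region present in the map; sums to width*height."""
    ids, counts = np.unique(amap.labels, return_counts=True)
    return {int(i): int(c) for i, c in zip(ids, counts)}


def assign_object_region(obj: ExtractedObject, amap: AtlasMap) -> int:
    """Region under the object's top-left (anchor) pixel."""
    x, y = obj.anchor_pixel
    if not (0 <= x < amap.width and 0 <= y < amap.height):
        raise GeometryError(
            f"object {obj.object_id}: anchor ({x}, {y}) outside "
            f"{amap.width}x{amap.height} map — dimensions not matched?"
        )
    return int(amap.labels[y, x])


def pixelwise_region_areas(
    objects: Sequence[ExtractedObject], amap: AtlasMap
) -> dict[int, int]:
    """Labelled-pixel count per region, attributing every pixel individually."""
    counts: Counter[int] = Counter()
    w, h = amap.width, amap.height
    labels = amap.labels
    for obj in objects:
        for x, y in obj.pixels:
            if not (0 <= x < w and 0 <= y < h):
                raise GeometryError(
                    f"object {obj.object_id}: pixel ({x}, {y}) outside "
                    f"{w}x{h} map"
                )
            counts[int(labels[y, x])] += 1
    return dict(counts)


def build_region_reports(
    objects: Sequence[ExtractedObject],
    amap: AtlasMap,
    table: LabelTable,
    scale: ScaleSpec,
    attribution: str = "pixel",
    include_zero_area: bool = False,
) -> list[RegionReport]:
    """One :class:`RegionReport` per region, sorted by region id.

    Regions absent from the map are omitted unless ``include_zero_area``.
    """
    if attribution not in ATTRIBUTION_MODES:
        raise ParameterError(f"attribution must be one of {ATTRIBUTION_MODES}")
    region_areas = region_pixel_areas(amap)
    anchor_regions = [assign_object_region(obj, amap) for obj in objects]
    counts = Counter(anchor_regions)
    if attribution == "pixel":
        object_areas = pixelwise_region_areas(objects, amap)
    else:
        object_areas = Counter()
        for obj, rid in zip(objects, anchor_regions):
            object_areas[rid] += obj.area_px
    region_ids = set(region_areas)
    if include_zero_area:
        region_ids |= set(table.ids)
    reports = []
    for rid in sorted(region_ids):
        rec = table.by_id(rid)
        reports.append(
            _make_report(
                rid, rec.name, rec.acronym,
                region_areas.get(rid, 0),
                counts.get(rid, 0),
                object_areas.get(rid, 0),
                scale,
            )
        )
    return reports


def whole_section_summary(
    reports: Sequence[RegionReport],
    scale: ScaleSpec,
    exclude_ids: Sequence[int] = (),
    name: str = "WHOLE_SECTION",
) -> RegionReport:
    """Summary row pooling all listed regions except ``exclude_ids``.

    The load is the area-weighted pooled fraction (summed object area over
    summed region area), not a mean of per-region loads.
    """
    excluded = set(exclude_ids)
    rows = [r for r in reports if r.region_id not in excluded]
    return _make_report(
        SUMMARY_REGION_ID, name, name,
        sum(r.region_area_px for r in rows),
        sum(r.object_count for r in rows),
        sum(r.object_area_px for r in rows),
        scale,
    )


# ---------------------------------------------------------------------------
# custom regions


@dataclass(frozen=True)
class CustomRegionSpec:
    """User-defined merged groups and exclusions over region ids."""

    groups: tuple[tuple[str, tuple[int, ...]], ...] = ()
    excluded: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for gname, members in self.groups:
            mset = set(members)
            if seen & mset:
                raise SpecError(
                    f"group {gname!r} overlaps another group on ids "
                    f"{sorted(seen & mset)}"
                )
            seen |= mset
        if seen & set(self.excluded):
            raise SpecError(
                f"excluded ids overlap groups: {sorted(seen & set(self.excluded))}"
            )

    @property
    def member_ids(self) -> set[int]:
        return {m for _, members in self.groups for m in members}


def load_custom_regions(path: str | Path, table: LabelTable) -> CustomRegionSpec:
    """Read a custom-region CSV: ``group_name,member_ids`` with members
    semicolon-separated.  A member token ``<id>+`` expands to the id plus all
    its descendants in the table hierarchy; the pseudo-group ``EXCLUDE``
    collects excluded ids."""
    groups: list[tuple[str, tuple[int, ...]]] = []
    excluded: list[int] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip() for c in header[:2]] != ["group_name", "member_ids"]:
            raise SpecError(f"{path}: header must be group_name,member_ids")
        for row in reader:
            if not row or not row[0].strip():
                continue
            gname = row[0].strip()
            members: list[int] = []
            for token in (row[1] if len(row) > 1 else "").split(";"):
                token = token.strip()
                if not token:
                    continue
                expand = token.endswith("+")
                try:
                    rid = int(token.rstrip("+"))
                except ValueError as exc:
                    raise SpecError(f"{path}: bad member token {token!r}") from exc
                if rid not in table:
                    raise SpecError(f"{path}: unknown region id {rid} in group {gname!r}")
                ids = sorted(table.descendants(rid, include_self=True)) if expand else [rid]
                members.extend(i for i in ids if i not in members)
            if gname == "EXCLUDE":
                excluded.extend(members)
            else:
                groups.append((gname, tuple(members)))
    return CustomRegionSpec(groups=tuple(groups), excluded=tuple(excluded))


def apply_custom_regions(
    reports: Sequence[RegionReport],
    spec: CustomRegionSpec,
    table: LabelTable,
    scale: ScaleSpec,
) -> list[RegionReport]:
    """Merge grouped regions (area-weighted) and drop excluded ones.

    Group load is ``sum(object areas) / sum(region areas)`` — *not* the mean
    of member loads.  Regions in no group and not excluded pass through.
    """
    for _, members in spec.groups:
        for rid in members:
            if rid not in table:
                raise SpecError(f"unknown region id {rid} in custom-region spec")
    for rid in spec.excluded:
        if rid not in table:
            raise SpecError(f"unknown excluded region id {rid}")
    by_id = {r.region_id: r for r in reports}
    out: list[RegionReport] = []
    for gname, members in spec.groups:
        rows = [by_id[m] for m in members if m in by_id]
        out.append(
            _make_report(
                None, gname, gname,
                sum(r.region_area_px for r in rows),
                sum(r.object_count for r in rows),
                sum(r.object_area_px for r in rows),
                scale,
            )
        )
    grouped = spec.member_ids
    dropped = set(spec.excluded)
    for r in reports:
        if r.region_id in grouped or r.region_id in dropped:
            continue
        out.append(r)
    return out


def aggregate_series(
    per_section: Sequence[Sequence[RegionReport]],
    scale: ScaleSpec,
) -> list[RegionReport]:
    """Pool per-section reports into one series report.

    Areas and counts are summed per region across sections; the series load
    is recomputed from the pooled sums, so a region present in only some
    sections is divided by its area in those sections only.
    """
    identity: dict[int | None, tuple[str, str]] = {}
    area: Counter = Counter()
    count: Counter = Counter()
    obj_area: Counter = Counter()
    keys: list[int | None] = []
    for reports in per_section:
        for r in reports:
            key = r.region_id if r.region_id is not None else ("group", r.name)
            ident = (r.name, r.acronym)
            if key in identity:
                if identity[key] != ident:
                    raise AggregationError(
                        f"region {key}: inconsistent identity {identity[key]} vs {ident}"
                    )
            else:
                identity[key] = ident
                keys.append(key)
            area[key] += r.region_area_px
            count[key] += r.object_count
            obj_area[key] += r.object_area_px
    out = []
    for key in sorted(keys, key=lambda k: (isinstance(k, tuple), k if not isinstance(k, tuple) else k[1])):
        name, acronym = identity[key]
        rid = None if isinstance(key, tuple) else key
        out.append(
            _make_report(rid, name, acronym, area[key], count[key], obj_area[key], scale)
        )
    return out


# ---------------------------------------------------------------------------
# report CSVs


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return format(float(value), ".6g")


def write_report_csv(reports: Sequence[RegionReport], path: str | Path) -> None:
    """Write reports in the documented schema: integers exact, floats with six
    significant digits, undefined loads as empty cells."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REPORT_COLUMNS)
        for r in reports:
            writer.writerow(
                [
                    "" if r.region_id is None else r.region_id,
                    r.name, r.acronym,
                    r.region_area_px, _fmt(r.region_area_um2),
                    r.object_count,
                    r.object_area_px, _fmt(r.object_area_um2),
                    _fmt(r.load),
                ]
            )


# ---------------------------------------------------------------------------
# point-grid (stereological) area-fraction estimator


@dataclass(frozen=True)
class PointGridEstimate:
    """Result of the point-counting probe: ``fraction`` is ``None`` when no
    test point landed on the section."""

    fraction: float | None
    positive_points: int
    total_points: int


def _point_positions(extent_um: float, grid_um: float, frame_um: float,
                     spacing_um: float) -> np.ndarray:
    frame_origins = np.arange(0.0, extent_um, grid_um)
    n_in_frame = int(math.ceil(frame_um / spacing_um))
    offsets = np.arange(n_in_frame) * spacing_um
    return (frame_origins[:, None] + offsets[None, :]).ravel()


def point_grid_area_fraction(
    mask: SegmentationMask,
    scale: ScaleSpec,
    grid_um: tuple[float, float] = (300.0, 300.0),
    frame_um: tuple[float, float] = (200.0, 200.0),
    point_spacing_um: float = 20.0,
) -> PointGridEstimate:
    """Estimate the labelled area fraction with a regular point grid.

    Counting frames of ``frame_um`` are laid at the ``grid_um`` period from
    the image origin; inside each frame, test points sit on a
    ``point_spacing_um`` lattice.  A point is positive when the mask pixel
    under it is a member.  Points falling outside the image are not counted.
    """
    if point_spacing_um <= 0 or any(g <= 0 for g in grid_um) or any(f <= 0 for f in frame_um):
        raise ParameterError("grid, frame and point spacing must be positive")
    if frame_um[0] > grid_um[0] or frame_um[1] > grid_um[1]:
        raise ParameterError(
            f"counting frame {frame_um} exceeds sampling grid {grid_um}"
        )
    um = scale.um_per_px
    xs_um = _point_positions(mask.width * um, grid_um[0], frame_um[0], point_spacing_um)
    ys_um = _point_positions(mask.height * um, grid_um[1], frame_um[1], point_spacing_um)
    xs = np.floor(xs_um / um).astype(np.intp)
    ys = np.floor(ys_um / um).astype(np.intp)
    xs = xs[xs < mask.width]
    ys = ys[ys < mask.height]
    total = int(xs.size * ys.size)
    if total == 0:
        return PointGridEstimate(fraction=None, positive_points=0, total_points=0)
    positive = int(mask.member[np.ix_(ys, xs)].sum())
    return PointGridEstimate(
        fraction=positive / total, positive_points=positive, total_points=total
    )


def section_pixel_fraction(mask: SegmentationMask) -> float:
    """Exact pixel-counted labelled fraction (reference for the estimator)."""
    return mask.member_count / (mask.width * mask.height)


def objects_to_csv(
    objects: Sequence[ExtractedObject],
    table: LabelTable,
    path: str | Path,
) -> None:
    """Per-object table: one row per extracted object with stats and region."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["object_id", "x_anchor", "y_anchor", "x_centroid", "y_centroid",
             "width_px", "height_px", "area_px", "area_um2", "region_id",
             "region_acronym"]
        )
        for obj in objects:
            acronym = ""
            if obj.region_id is not None and obj.region_id in table:
                acronym = table.by_id(obj.region_id).acronym
            writer.writerow(
                [
                    obj.object_id,
                    obj.anchor_pixel[0], obj.anchor_pixel[1],
                    _fmt(obj.centroid[0]), _fmt(obj.centroid[1]),
                    obj.width_px, obj.height_px, obj.area_px,
                    _fmt(obj.area_um2),
                    "" if obj.region_id is None else obj.region_id,
                    acronym,
                ]
            )
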