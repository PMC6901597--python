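"""Synthetic test scenes with exactly known ground truth.

Generates label tables, atlas maps, colour segmentations and anchoring files
in the package's own dialects, together with planted per-region counts,
areas and loads under both attribution rules.  Everything is derived from a
single integer seed, so regeneration is byte-identical, and the region
tiling always contains concave regions (an L-shaped notch) so boundary and
pixelwise-attribution code paths get exercised.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .atlas_io import (
    AtlasMap,
    LabelTable,
    RegionRecord,
    SectionAnchor,
    serialize_anchoring,
    write_atlas_map,
)
from .errors import GenerationError, ParameterError
from .transform import ScaleSpec

DEFAULT_TARGET_COLOUR = (255, 0, 255)
_PARENT_IDS = (1001, 1002)
_N4 = ((1, 0), (-1, 0), (0, 1), (0, -1))


def _palette(n: int) -> list[tuple[int, int, int]]:
    colours: list[tuple[int, int, int]] = []
    i = 0
    while len(colours) < n:
        c = ((37 * i + 63) % 256, (101 * i + 89) % 256, (173 * i + 131) % 256)
        i += 1
        if c != (0, 0, 0) and c != DEFAULT_TARGET_COLOUR and c not in colours:
            colours.append(c)
    return colours


def make_label_table(n_regions: int) -> LabelTable:
    """Two-level hierarchy: children 1..n under two parent groups."""
    if n_regions < 1:
        raise ParameterError(f"n_regions must be >= 1, got {n_regions}")
    n_parents = min(2, n_regions)
    colours = _palette(n_regions + n_parents)
    records = [RegionRecord(0, "background", "bg", (0, 0, 0), None)]
    for j in range(n_parents):
        records.append(
            RegionRecord(_PARENT_IDS[j], f"group_{'AB'[j]}", f"G{'AB'[j]}",
                         colours[n_regions + j], None)
        )
    for i in range(n_regions):
        records.append(
            RegionRecord(i + 1, f"region_{i + 1}", f"R{i + 1}", colours[i],
                         _PARENT_IDS[i % n_parents])
        )
    return LabelTable(records)


def _tile_regions(width: int, height: int, child_ids: list[int],
                  border: int = 3) -> np.ndarray:
    n = len(child_ids)
    iw = width - 2 * border
    ih = height - 2 * border
    if iw < 4 * n or ih < 8:
        raise GenerationError(
            f"{width}x{height} too small to tile {n} regions with border {border}"
        )
    labels = np.zeros((height, width), dtype=np.int64)
    strip = iw // n
    x0 = border
    for i, cid in enumerate(child_ids):
        x1 = border + iw if i == n - 1 else x0 + strip
        labels[border:height - border, x0:x1] = cid
        x0 = x1
    if n >= 2:
        # notch makes regions 1 and 2 concave (L-shaped / bitten)
        notch_w = max(1, strip // 2)
        notch_h = max(1, ih // 3)
        nx = border + strip
        labels[border:border + notch_h, nx:nx + notch_w] = child_ids[0]
    return labels


def _grow_blob(
    rng: np.random.Generator,
    labels: np.ndarray,
    occupied: np.ndarray,
    start: tuple[int, int],
    target: int,
    restrict_region: int | None,
) -> set[tuple[int, int]]:
    h, w = labels.shape
    chosen: set[tuple[int, int]] = set()
    frontier: list[tuple[int, int]] = [start]
    while frontier and len(chosen) < target:
        i = int(rng.integers(len(frontier)))
        x, y = frontier.pop(i)
        if (x, y) in chosen or not (0 <= x < w and 0 <= y < h):
            continue
        if occupied[y, x]:
            continue
        lab = int(labels[y, x])
        if lab == 0 or (restrict_region is not None and lab != restrict_region):
            continue
        chosen.add((x, y))
        for dx, dy in _N4:
            frontier.append((x + dx, y + dy))
    return chosen


@dataclass(frozen=True)
class SyntheticScene:
    """One synthetic section with planted, closed-form ground truth."""

    seed: int
    width: int
    height: int
    section_number: int
    table: LabelTable
    atlas: AtlasMap
    anchor: SectionAnchor
    objects: tuple[tuple[tuple[int, int], ...], ...]  # per-object raster-sorted pixels
    target_colour: tuple[int, int, int]

    @property
    def image_name(self) -> str:
        return f"img_s{self.section_number:03d}.png"

    @property
    def atlas_name(self) -> str:
        return f"atlas_s{self.section_number:03d}"

    @property
    def labelled_pixel_count(self) -> int:
        return sum(len(o) for o in self.objects)

    def segmentation_array(self) -> np.ndarray:
        img = np.full((self.height, self.width, 3), 255, dtype=np.uint8)
        for pixels in self.objects:
            for x, y in pixels:
                img[y, x] = self.target_colour
        return img

    # -- ground truth (direct arithmetic on planted pixels) --------------

    def truth_region_areas(self) -> dict[int, int]:
        ids, counts = np.unique(self.atlas.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    def truth_object_anchor_regions(self) -> list[int]:
        return [
            int(self.atlas.labels[pixels[0][1], pixels[0][0]])
            for pixels in self.objects
        ]

    def truth_report(self, attribution: str = "pixel") -> dict[int, dict[str, int]]:
        """Per-region ``object_count`` and ``object_area_px`` under a rule."""
        counts: Counter[int] = Counter(self.truth_object_anchor_regions())
        areas: Counter[int] = Counter()
        if attribution == "anchor":
            for pixels, rid in zip(self.objects, self.truth_object_anchor_regions()):
                areas[rid] += len(pixels)
        elif attribution == "pixel":
            for pixels in self.objects:
                for x, y in pixels:
                    areas[int(self.atlas.labels[y, x])] += 1
        else:
            raise ParameterError(f"unknown attribution {attribution!r}")
        out: dict[int, dict[str, int]] = {}
        for rid in set(counts) | set(areas):
            out[rid] = {
                "object_count": counts.get(rid, 0),
                "object_area_px": areas.get(rid, 0),
            }
        return out

    def truth_loads(self, attribution: str = "pixel") -> dict[int, float]:
        region_areas = self.truth_region_areas()
        return {
            rid: row["object_area_px"] / region_areas[rid]
            for rid, row in self.truth_report(attribution).items()
            if region_areas.get(rid, 0) > 0
        }


def _random_anchor(rng: np.random.Generator, name: str, width: int,
                   height: int) -> SectionAnchor:
    o = tuple(float(c) for c in rng.uniform(0.0, 300.0, 3))
    u = (float(rng.uniform(30.0, 60.0)), float(rng.uniform(-2.0, 2.0)),
         float(rng.uniform(-2.0, 2.0)))
    v = (float(rng.uniform(-2.0, 2.0)), float(rng.uniform(-2.0, 2.0)),
         -float(rng.uniform(30.0, 60.0)))
    return SectionAnchor(name, width, height, o, u, v)


def make_scene(
    seed: int,
    width: int = 128,
    height: int = 128,
    n_regions: int = 4,
    n_objects: int = 10,
    object_size_range: tuple[int, int] = (5, 40),
    straddle_fraction: float = 0.0,
    target_colour: tuple[int, int, int] = DEFAULT_TARGET_COLOUR,
    section_number: int = 1,
    table: LabelTable | None = None,
    anchor: SectionAnchor | None = None,
) -> SyntheticScene:
    """Plant ``n_objects`` irregular blobs on a tiled atlas map.

    ``straddle_fraction`` of the objects are forced to cross a region border
    (exercising the anchor-vs-pixel attribution discrepancy); the rest are
    confined to a single region.  Objects are grown 4-connected and kept at
    Chebyshev distance >= 2 from each other, so extraction recovers exactly
    the planted partition under either connectivity.
    """
    if width < 1 or height < 1 or n_objects < 0:
        raise ParameterError("sizes must be positive")
    if not 0.0 <= straddle_fraction <= 1.0:
        raise ParameterError(f"straddle_fraction must be in [0, 1], got {straddle_fraction}")
    lo, hi = object_size_range
    if not 1 <= lo <= hi:
        raise ParameterError(f"bad object_size_range {object_size_range}")
    rng = np.random.default_rng(seed)
    if table is None:
        table = make_label_table(n_regions)
    child_ids = sorted(i for i in table.ids if 0 < i < min(_PARENT_IDS))
    labels = _tile_regions(width, height, child_ids)

    nonzero = labels != 0
    internal = np.zeros_like(nonzero)
    diff_r = nonzero[:, :-1] & nonzero[:, 1:] & (labels[:, :-1] != labels[:, 1:])
    internal[:, :-1] |= diff_r
    internal[:, 1:] |= diff_r
    diff_d = nonzero[:-1, :] & nonzero[1:, :] & (labels[:-1, :] != labels[1:, :])
    internal[:-1, :] |= diff_d
    internal[1:, :] |= diff_d
    boundary_px = np.argwhere(internal)  # (y, x) adjacent to a different region
    interior_px = np.argwhere(nonzero)
    if interior_px.size == 0:
        raise GenerationError("atlas map has no non-background pixels")

    n_straddle = int(round(straddle_fraction * n_objects))
    if n_straddle > 0 and boundary_px.size == 0:
        raise GenerationError("no region borders available for straddling objects")

    occupied = np.zeros_like(nonzero)
    planted: list[tuple[tuple[int, int], ...]] = []
    for k in range(n_objects):
        straddler = k < n_straddle
        target = int(rng.integers(lo, hi + 1))
        cands = boundary_px if straddler else interior_px
        chosen: set[tuple[int, int]] = set()
        for _attempt in range(300):
            y, x = (int(c) for c in cands[int(rng.integers(len(cands)))])
            if occupied[y, x]:
                continue
            restrict = None if straddler else int(labels[y, x])
            chosen = _grow_blob(rng, labels, occupied, (x, y), target, restrict)
            if len(chosen) < target:
                continue
            if straddler and len({int(labels[py, px]) for px, py in chosen}) < 2:
                continue
            break
        else:
            raise GenerationError(
                f"could not place object {k + 1}/{n_objects} "
                f"(size {target}, straddler={straddler})"
            )
        for x, y in chosen:
            occupied[max(0, y - 1):y + 2, max(0, x - 1):x + 2] = True
        planted.append(tuple(sorted(chosen, key=lambda p: (p[1], p[0]))))
    planted.sort(key=lambda px: (px[0][1], px[0][0]))  # raster order of anchors

    name = f"img_s{section_number:03d}.png"
    if anchor is None:
        anchor = _random_anchor(rng, name, width, height)
    return SyntheticScene(
        seed=seed,
        width=width,
        height=height,
        section_number=section_number,
        table=table,
        atlas=AtlasMap(labels),
        anchor=anchor,
        objects=tuple(planted),
        target_colour=tuple(target_colour),
    )


@dataclass(frozen=True)
class SyntheticSeries:
    """Serial sections sharing one label table, with pooled ground truth."""

    seed: int
    table: LabelTable
    scenes: tuple[SyntheticScene, ...]

    def pooled_region_areas(self) -> dict[int, int]:
        out: Counter[int] = Counter()
        for scene in self.scenes:
            out.update(scene.truth_region_areas())
        return dict(out)

    def pooled_report(self, attribution: str = "pixel") -> dict[int, dict[str, int]]:
        out: dict[int, dict[str, int]] = {}
        for scene in self.scenes:
            for rid, row in scene.truth_report(attribution).items():
                acc = out.setdefault(rid, {"object_count": 0, "object_area_px": 0})
                acc["object_count"] += row["object_count"]
                acc["object_area_px"] += row["object_area_px"]
        return out

    def pooled_loads(self, attribution: str = "pixel") -> dict[int, float]:
        areas = self.pooled_region_areas()
        return {
            rid: row["object_area_px"] / areas[rid]
            for rid, row in self.pooled_report(attribution).items()
            if areas.get(rid, 0) > 0
        }


def make_series(
    seed: int,
    n_sections: int,
    drift: float = 0.0,
    section_spacing: float = 8.0,
    start_number: int = 10,
    number_step: int = 4,
    **scene_kwargs,
) -> SyntheticSeries:
    """Serial coronal-style sections: ``o`` advances along a fixed axis,
    ``u``/``v`` get Gaussian jitter scaled by ``drift`` (0 = parallel planes)."""
    if n_sections < 1:
        raise ParameterError(f"n_sections must be >= 1, got {n_sections}")
    rng = np.random.default_rng(seed)
    n_regions = scene_kwargs.get("n_regions", 4)
    table = make_label_table(n_regions)
    width = scene_kwargs.get("width", 128)
    height = scene_kwargs.get("height", 128)
    base_o = rng.uniform(0.0, 100.0, 3)
    base_u = np.array([50.0, 0.0, 0.0])
    base_v = np.array([0.0, 0.0, -40.0])
    axis = np.array([0.0, 1.0, 0.0])
    scenes = []
    for i in range(n_sections):
        num = start_number + i * number_step
        o = base_o + i * section_spacing * axis
        u = base_u + drift * rng.normal(0.0, 1.0, 3)
        v = base_v + drift * rng.normal(0.0, 1.0, 3)
        anchor = SectionAnchor(
            f"img_s{num:03d}.png", width, height,
            tuple(float(c) for c in o),
            tuple(float(c) for c in u),
            tuple(float(c) for c in v),
        )
        scene_seed = int(rng.integers(0, 2**31 - 1))
        scenes.append(
            make_scene(scene_seed, section_number=num, table=table,
                       anchor=anchor, **scene_kwargs)
        )
    return SyntheticSeries(seed=seed, table=table, scenes=tuple(scenes))


# ---------------------------------------------------------------------------
# writing a ready-to-run input tree


def _write_ground_truth(series: SyntheticSeries, path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["section", "attribution", "region_id", "region_area_px",
             "object_count", "object_area_px", "load"]
        )
        for attribution in ("pixel", "anchor"):
            for scene in series.scenes:
                areas = scene.truth_region_areas()
                report = scene.truth_report(attribution)
                for rid in sorted(areas):
                    row = report.get(rid, {"object_count": 0, "object_area_px": 0})
                    load = row["object_area_px"] / areas[rid] if areas[rid] else ""
                    writer.writerow(
                        [f"s{scene.section_number:03d}", attribution, rid,
                         areas[rid], row["object_count"], row["object_area_px"],
                         load]
                    )
            pooled_areas = series.pooled_region_areas()
            pooled = series.pooled_report(attribution)
            for rid in sorted(pooled_areas):
                row = pooled.get(rid, {"object_count": 0, "object_area_px": 0})
                load = row["object_area_px"] / pooled_areas[rid] if pooled_areas[rid] else ""
                writer.writerow(
                    ["SERIES", attribution, rid, pooled_areas[rid],
                     row["object_count"], row["object_area_px"], load]
                )


def _config_toml(series: SyntheticSeries, scale: ScaleSpec,
                 atlas_mode: str) -> str:
    colour = series.scenes[0].target_colour
    return (
        'segmentation_dir = "segmentations"\n'
        'atlas_dir = "atlas"\n'
        'anchoring = "anchoring.xml"\n'
        'label_table = "label_table.csv"\n'
        'output_dir = "output"\n'
        f"base_pixel_size = {scale.base_pixel_size}\n"
        f"resize_factor = {scale.resize_factor}\n"
        f'atlas_mode = "{atlas_mode}"\n'
        f"target_colours = [[{colour[0]}, {colour[1]}, {colour[2]}]]\n"
    )


def write_series(
    series: SyntheticSeries,
    root: str | Path,
    atlas_mode: str = "colour",
    scale: ScaleSpec = ScaleSpec(1.0, 1.0),
) -> dict[str, Path]:
    """Write the complete input tree: segmentations, atlas maps, anchoring,
    label table, a ready-to-run ``config.toml`` and ``ground_truth.csv``."""
    root = Path(root)
    seg_dir = root / "segmentations"
    atlas_dir = root / "atlas"
    seg_dir.mkdir(parents=True, exist_ok=True)
    atlas_dir.mkdir(parents=True, exist_ok=True)
    for scene in series.scenes:
        Image.fromarray(scene.segmentation_array()).save(seg_dir / scene.image_name)
        ext = ".png" if atlas_mode == "colour" else ".qmap"
        write_atlas_map(scene.atlas, atlas_dir / (scene.atlas_name + ext),
                        table=series.table, mode=atlas_mode)
    series.table.to_csv(root / "label_table.csv")
    serialize_anchoring([s.anchor for s in series.scenes], root / "anchoring.xml")
    _write_ground_truth(series, root / "ground_truth.csv")
    (root / "config.toml").write_text(
        _config_toml(series, scale, atlas_mode), encoding="utf-8"
    )
    return {
        "segmentations": seg_dir,
        "atlas": atlas_dir,
        "anchoring": root / "anchoring.xml",
        "label_table": root / "label_table.csv",
        "ground_truth": root / "ground_truth.csv",
        "config": root / "config.toml",
    }


def write_scene(scene: SyntheticScene, root: str | Path, **kwargs) -> dict[str, Path]:
    """Single-section convenience wrapper around :func:`write_series`."""
    series = SyntheticSeries(seed=scene.seed, table=scene.table, scenes=(scene,))
    return write_series(series, root, **kwargs)
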