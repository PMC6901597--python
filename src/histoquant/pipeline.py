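"""End-to-end quantification run.

For every matched section: load segmentation and atlas map, rescale the map
to the segmentation's dimensions, binarise each target colour, extract and
size-filter objects, assign regions, write per-section reports and overlays,
and accumulate atlas-space points.  Sections fail independently: one bad
file is recorded in the manifest and the run continues, exiting non-zero.

Determinism: directory listings are sorted, no wall-clock values enter any
scientific output, and all float formatting is fixed, so two runs from one
config produce bit-identical CSV/TSV/JSON artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import __version__
from .atlas_io import (
    load_atlas_map,
    load_label_table,
    match_sections,
    parse_anchoring,
    rescale_atlas_map,
)
from .config import RunConfig
from .coordinates import AtlasPoint, export_point_cloud, object_points
from .errors import FormatError, HistoQuantError
from .objects import ExtractedObject, binarize_by_colour, extract_objects, filter_by_size
from .overlay import OverlayStyle, render_overlay
from .quantify import (
    RegionReport,
    aggregate_series,
    apply_custom_regions,
    assign_object_region,
    build_region_reports,
    load_custom_regions,
    objects_to_csv,
    whole_section_summary,
    write_report_csv,
)

logger = logging.getLogger(__name__)

_IMAGE_SUFFIXES = (".png",)
_MAP_SUFFIXES = (".png", ".qmap")


@dataclass
class RunResult:
    """Structured outcome of :func:`run_quantifier`."""

    exit_code: int
    manifest: dict
    section_reports: dict[int, list[RegionReport]] = field(default_factory=dict)
    section_objects: dict[int, list[ExtractedObject]] = field(default_factory=dict)
    series_reports: list[RegionReport] = field(default_factory=list)
    points: list[AtlasPoint] = field(default_factory=list)
    failures: dict[int, str] = field(default_factory=dict)


def _load_segmentation(path: Path) -> np.ndarray:
    img = Image.open(path)
    if img.mode != "RGB":
        raise FormatError(
            f"{path.name}: segmentations must be 24-bit colour PNG images "
            f"(got mode {img.mode})"
        )
    return np.asarray(img)


def run_quantifier(config: RunConfig) -> RunResult:
    """Execute the full quantification pipeline described by ``config``."""
    config.validate_paths()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scale = config.scale

    table = load_label_table(config.label_table)
    anchors = parse_anchoring(config.anchoring)
    images = sorted(
        p.name for p in Path(config.segmentation_dir).iterdir()
        if p.suffix.lower() in _IMAGE_SUFFIXES
    )
    maps = sorted(
        p.name for p in Path(config.atlas_dir).iterdir()
        if p.suffix.lower() in _MAP_SUFFIXES
    )
    match = match_sections(images, anchors, maps, config.section_pattern)
    custom = (
        load_custom_regions(config.custom_regions, table)
        if config.custom_regions is not None else None
    )

    result = RunResult(exit_code=0, manifest={})
    section_infos: list[dict] = []
    style = OverlayStyle(atlas_alpha=config.atlas_alpha)

    for triple in match.triples:
        key = triple.key
        tag = f"s{key:03d}"
        try:
            image = _load_segmentation(Path(config.segmentation_dir) / triple.image)
            amap = load_atlas_map(
                Path(config.atlas_dir) / triple.map, table, config.atlas_mode
            )
            h, w = image.shape[:2]
            if (amap.width, amap.height) != (w, h):
                amap = rescale_atlas_map(amap, w, h)

            extracted: list[ExtractedObject] = []
            for colour in config.target_colours:
                mask = binarize_by_colour(image, colour)
                extracted.extend(
                    extract_objects(mask, config.connectivity, scale)
                )
            kept, rejected = filter_by_size(extracted, config.min_px, config.max_px)
            kept = [
                obj.with_id(i + 1).with_region(assign_object_region(obj, amap))
                for i, obj in enumerate(kept)
            ]

            reports = build_region_reports(
                kept, amap, table, scale, attribution=config.attribution
            )
            out_reports = (
                apply_custom_regions(reports, custom, table, scale)
                if custom is not None else list(reports)
            )
            out_reports.append(
                whole_section_summary(
                    reports, scale, exclude_ids=(table.background_id,)
                )
            )

            objects_to_csv(kept, table, out_dir / f"{tag}_objects.csv")
            write_report_csv(out_reports, out_dir / f"{tag}_report.csv")
            Image.fromarray(render_overlay(amap, kept, table, style)).save(
                out_dir / f"{tag}_overlay.png"
            )
            result.points.extend(
                object_points(
                    kept, triple.anchor,
                    granularity=config.export_granularity,
                    convention=config.convention,
                )
            )
            result.section_reports[key] = reports
            result.section_objects[key] = kept
            section_infos.append(
                {
                    "section": tag,
                    "image": triple.image,
                    "map": triple.map,
                    "status": "ok",
                    "objects_extracted": len(extracted),
                    "objects_kept": len(kept),
                    "objects_rejected": len(rejected),
                    "labelled_px_kept": sum(o.area_px for o in kept),
                }
            )
            logger.info("%s: %d objects kept (%d rejected)", tag, len(kept), len(rejected))
        except (HistoQuantError, OSError) as exc:
            result.failures[key] = str(exc)
            section_infos.append(
                {"section": tag, "image": triple.image, "map": triple.map,
                 "status": "failed", "error": str(exc)}
            )
            logger.error("%s failed: %s", tag, exc)

    if result.section_reports:
        series = aggregate_series(list(result.section_reports.values()), scale)
        series_out = (
            apply_custom_regions(series, custom, table, scale)
            if custom is not None else list(series)
        )
        series_out.append(
            whole_section_summary(
                series, scale, exclude_ids=(table.background_id,),
                name="WHOLE_SERIES",
            )
        )
        result.series_reports = series
        write_report_csv(series_out, out_dir / "series_report.csv")

    export_point_cloud(
        result.points, out_dir / "points.tsv", fmt="tsv",
        subsample=config.export_subsample,
    )
    export_point_cloud(
        result.points, out_dir / "points.json", fmt="json",
        subsample=config.export_subsample, table=table,
    )

    failed = bool(result.failures) or bool(match.unmatched_images)
    result.exit_code = 1 if failed else 0
    result.manifest = {
        "software": "histoquant",
        "version": __version__,
        "config": config.to_dict(),
        "coordinate_unit": "atlas voxel",
        "sections": section_infos,
        "unmatched": {
            "images": list(match.unmatched_images),
            "anchors": list(match.unmatched_anchors),
            "maps": list(match.unmatched_maps),
        },
        "failures": {f"s{k:03d}": v for k, v in sorted(result.failures.items())},
        "totals": {
            "sections_processed": len(result.section_reports),
            "sections_failed": len(result.failures),
            "objects_kept": sum(
                info.get("objects_kept", 0) for info in section_infos
            ),
            "points_exported": len(result.points[::config.export_subsample]),
        },
        "exit_code": result.exit_code,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=1, sort_keys=True), encoding="utf-8"
    )
    return result
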