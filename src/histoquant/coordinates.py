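"""Mapping segmented pixels into 3D reference-atlas space.

Each section's anchoring gives an origin ``o`` and two in-plane vectors
``u`` (along image x) and ``v`` (along image y) in atlas voxel units.  A
pixel maps to ``o + u * fx + v * fy`` where ``(fx, fy)`` is its fractional
position in the image — pixel-centre fractions by default, corner fractions
(``x / width``) in compatibility mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .atlas_io import LabelTable, SectionAnchor
from .errors import GeometryError, ParameterError
from .objects import ExtractedObject

CONVENTIONS = ("centre", "corner")


@dataclass(frozen=True)
class AtlasPoint:
    """One exported point: atlas coordinates plus provenance."""

    x: float
    y: float
    z: float
    region_id: int | None
    section_key: str


def _fractions(xs: np.ndarray, ys: np.ndarray, anchor: SectionAnchor,
               convention: str) -> tuple[np.ndarray, np.ndarray]:
    if convention == "centre":
        return (xs + 0.5) / anchor.width, (ys + 0.5) / anchor.height
    if convention == "corner":
        return xs / anchor.width, ys / anchor.height
    raise ParameterError(f"convention must be one of {CONVENTIONS}, got {convention!r}")


def pixel_to_atlas(
    px: tuple[float, float],
    anchor: SectionAnchor,
    convention: str = "centre",
) -> tuple[float, float, float]:
    """Map one pixel to atlas coordinates.

    Bounds: ``0 <= x < width`` in centre mode; corner mode additionally
    admits the far edges (``x == width``) so that the image of ``(W, 0)``
    is exactly ``o + u``.
    """
    x, y = px
    hi_x = anchor.width if convention == "corner" else anchor.width - 1
    hi_y = anchor.height if convention == "corner" else anchor.height - 1
    if not (0 <= x <= hi_x and 0 <= y <= hi_y):
        raise GeometryError(
            f"pixel ({x}, {y}) outside {anchor.width}x{anchor.height} "
            f"section {anchor.section_key}"
        )
    fx, fy = _fractions(np.asarray(float(x)), np.asarray(float(y)), anchor, convention)
    o = np.asarray(anchor.o)
    u = np.asarray(anchor.u)
    v = np.asarray(anchor.v)
    out = o + u * float(fx) + v * float(fy)
    return (float(out[0]), float(out[1]), float(out[2]))


def pixels_to_atlas(
    pixels: Sequence[tuple[int, int]],
    anchor: SectionAnchor,
    convention: str = "centre",
) -> np.ndarray:
    """Vectorised :func:`pixel_to_atlas`; returns an (n, 3) array."""
    if len(pixels) == 0:
        return np.zeros((0, 3))
    arr = np.asarray(pixels, dtype=float)
    xs, ys = arr[:, 0], arr[:, 1]
    hi_x = anchor.width if convention == "corner" else anchor.width - 1
    hi_y = anchor.height if convention == "corner" else anchor.height - 1
    if xs.min() < 0 or ys.min() < 0 or xs.max() > hi_x or ys.max() > hi_y:
        raise GeometryError(
            f"pixel outside {anchor.width}x{anchor.height} section "
            f"{anchor.section_key}"
        )
    fx, fy = _fractions(xs, ys, anchor, convention)
    o = np.asarray(anchor.o)
    u = np.asarray(anchor.u)
    v = np.asarray(anchor.v)
    return o[None, :] + fx[:, None] * u[None, :] + fy[:, None] * v[None, :]


def object_points(
    objects: Sequence[ExtractedObject],
    anchor: SectionAnchor,
    granularity: str = "pixel",
    convention: str = "centre",
) -> list[AtlasPoint]:
    """Atlas points for a section's objects.

    ``pixel`` granularity emits one point per member pixel; ``centroid``
    emits one point per object at its transformed centroid.  Ordering is
    deterministic: object order, then raster order of pixels.
    """
    if granularity not in ("pixel", "centroid"):
        raise ParameterError(f"granularity must be 'pixel' or 'centroid', got {granularity!r}")
    points: list[AtlasPoint] = []
    for obj in objects:
        if granularity == "pixel":
            coords = pixels_to_atlas(obj.pixels, anchor, convention)
        else:
            coords = pixels_to_atlas([obj.centroid], anchor, convention)
        for row in coords:
            points.append(
                AtlasPoint(float(row[0]), float(row[1]), float(row[2]),
                           obj.region_id, anchor.section_key)
            )
    return points


def export_point_cloud(
    points: Sequence[AtlasPoint],
    path: str | Path,
    fmt: str = "tsv",
    subsample: int = 1,
    table: LabelTable | None = None,
) -> None:
    """Write a point cloud for an external atlas viewer.

    ``subsample`` keeps every k-th point (deterministic, indices 0, k, 2k, …).
    TSV columns: x, y, z, region_id, section_key.  JSON groups points by
    region as ``[{"region_id":…, "name":…, "colour":[r,g,b],
    "points":[x, y, z, …]}, …]`` with colours from ``table``.
    """
    if subsample < 1:
        raise ParameterError(f"subsample must be >= 1, got {subsample}")
    kept = list(points)[::subsample]
    path = Path(path)
    if fmt == "tsv":
        lines = ["x\ty\tz\tregion_id\tsection_key"]
        for p in kept:
            rid = "" if p.region_id is None else str(p.region_id)
            lines.append(
                f"{p.x:.6f}\t{p.y:.6f}\t{p.z:.6f}\t{rid}\t{p.section_key}"
            )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return
    if fmt != "json":
        raise ParameterError(f"fmt must be 'tsv' or 'json', got {fmt!r}")
    grouped: dict[int | None, list[float]] = {}
    for p in kept:
        grouped.setdefault(p.region_id, []).extend((p.x, p.y, p.z))
    payload = []
    order = sorted(grouped, key=lambda r: (r is None, r if r is not None else 0))
    for rid in order:
        if table is not None and rid is not None and rid in table:
            rec = table.by_id(rid)
            name, colour = rec.name, list(rec.colour)
        else:
            name, colour = str(rid), [0, 0, 0]
        payload.append(
            {"region_id": rid, "name": name, "colour": colour,
             "points": [round(c, 6) for c in grouped[rid]]}
        )
    path.write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_point_cloud_tsv(path: str | Path) -> list[AtlasPoint]:
    """Inverse of the TSV export (coordinates to 1e-6)."""
    points = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        x, y, z, rid, key = line.split("\t")
        points.append(
            AtlasPoint(float(x), float(y), float(z),
                       int(rid) if rid else None, key)
        )
    return points
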