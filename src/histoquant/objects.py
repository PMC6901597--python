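"""Connected-component object extraction from colour segmentations.

A segmentation image marks each object class with one exact RGB colour.
Binarising by colour gives a mask; flood fill over the mask yields the
individual objects, each with its geometry statistics.  The fill is
iterative (explicit stack) so arbitrarily large blobs cannot overflow the
interpreter stack; semantics are plain 4- or 8-connected flood fill.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .transform import ScaleSpec, object_area_um2

logger = logging.getLogger(__name__)

_OFFSETS_4 = ((1, 0), (-1, 0), (0, 1), (0, -1))
_OFFSETS_8 = _OFFSETS_4 + ((1, 1), (1, -1), (-1, 1), (-1, -1))


@dataclass(frozen=True)
class SegmentationMask:
    """Boolean membership grid for one target colour of one segmentation."""

    member: np.ndarray  # (height, width) bool
    source_colour: tuple[int, int, int]

    @property
    def width(self) -> int:
        return int(self.member.shape[1])

    @property
    def height(self) -> int:
        return int(self.member.shape[0])

    @property
    def member_count(self) -> int:
        return int(self.member.sum())


@dataclass(frozen=True)
class ExtractedObject:
    """One connected cluster of labelled pixels and its statistics.

    ``pixels`` are (x, y) pairs sorted in raster order (y, then x); the
    anchor pixel is therefore ``pixels[0]``: smallest y, ties broken by
    smallest x ("top-left" rule).  ``bbox`` is inclusive at both ends.
    """

    object_id: int
    pixels: tuple[tuple[int, int], ...]
    area_px: int
    bbox: tuple[int, int, int, int]  # x_min, y_min, x_max, y_max
    width_px: int
    height_px: int
    centroid: tuple[float, float]
    anchor_pixel: tuple[int, int]
    area_um2: float | None = None
    region_id: int | None = None

    def with_region(self, region_id: int) -> "ExtractedObject":
        return replace(self, region_id=region_id)

    def with_id(self, object_id: int) -> "ExtractedObject":
        return replace(self, object_id=object_id)


def binarize_by_colour(
    image: np.ndarray, colour: tuple[int, int, int]
) -> SegmentationMask:
    """Exact-match mask of ``colour`` in a 24-bit RGB image."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ParameterError(
            f"expected 24-bit RGB image (HxWx3 uint8), got shape "
            f"{image.shape} dtype {image.dtype}"
        )
    colour = tuple(int(c) for c in colour)
    member = np.all(image == np.asarray(colour, dtype=np.uint8), axis=2)
    if not member.any():
        logger.warning("target colour %s absent from image", colour)
    return SegmentationMask(member=member, source_colour=colour)


def object_stats(
    pixels: Sequence[tuple[int, int]],
    scale: ScaleSpec | None = None,
    object_id: int = 0,
    region_id: int | None = None,
) -> ExtractedObject:
    """Complete the statistics of one pixel cluster.

    Centroid is the arithmetic mean of pixel coordinates; width/height are
    inclusive bounding-box extents; physical area needs ``scale``.
    """
    if not pixels:
        raise ParameterError("object must have at least one pixel")
    px = sorted((int(x), int(y)) for x, y in pixels)
    px.sort(key=lambda p: (p[1], p[0]))  # raster order: y, then x
    xs = [p[0] for p in px]
    ys = [p[1] for p in px]
    bbox = (min(xs), min(ys), max(xs), max(ys))
    n = len(px)
    return ExtractedObject(
        object_id=object_id,
        pixels=tuple(px),
        area_px=n,
        bbox=bbox,
        width_px=bbox[2] - bbox[0] + 1,
        height_px=bbox[3] - bbox[1] + 1,
        centroid=(sum(xs) / n, sum(ys) / n),
        anchor_pixel=px[0],
        area_um2=None if scale is None else object_area_um2(n, scale),
        region_id=region_id,
    )


def extract_objects(
    mask: SegmentationMask,
    connectivity: int = 8,
    scale: ScaleSpec | None = None,
) -> list[ExtractedObject]:
    """Separate a mask into maximal connected objects.

    Scans in raster order and flood-fills each unvisited member pixel with an
    explicit stack.  Because the raster scan reaches every component first at
    its top-left member pixel, objects come out numbered (from 1) in raster
    order of their anchor pixels.
    """
    if connectivity == 4:
        offsets = _OFFSETS_4
    elif connectivity == 8:
        offsets = _OFFSETS_8
    else:
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    h, w = mask.member.shape
    rows: list[list[bool]] = mask.member.tolist()
    visited = [[False] * w for _ in range(h)]
    objects: list[ExtractedObject] = []
    for y in range(h):
        row = rows[y]
        vrow = visited[y]
        for x in range(w):
            if not row[x] or vrow[x]:
                continue
            vrow[x] = True
            stack = [(x, y)]
            pixels: list[tuple[int, int]] = []
            while stack:
                cx, cy = stack.pop()
                pixels.append((cx, cy))
                for dx, dy in offsets:
                    nx = cx + dx
                    ny = cy + dy
                    if 0 <= nx < w and 0 <= ny < h and rows[ny][nx] \
                            and not visited[ny][nx]:
                        visited[ny][nx] = True
                        stack.append((nx, ny))
            objects.append(
                object_stats(pixels, scale=scale, object_id=len(objects) + 1)
            )
    return objects


def filter_by_size(
    objects: Sequence[ExtractedObject],
    min_px: int = 1,
    max_px: int | None = None,
) -> tuple[list[ExtractedObject], list[ExtractedObject]]:
    """Partition objects into (kept, rejected) by pixel area, inclusive bounds.

    Rejected objects are returned (not discarded) so runs can audit what the
    size cut-offs removed.
    """
    if max_px is None:
        max_px = np.iinfo(np.int64).max
    if not 1 <= min_px <= max_px:
        raise ParameterError(
            f"size bounds must satisfy 1 <= min <= max, got [{min_px}, {max_px}]"
        )
    kept: list[ExtractedObject] = []
    rejected: list[ExtractedObject] = []
    for obj in objects:
        (kept if min_px <= obj.area_px <= max_px else rejected).append(obj)
    return kept, rejected
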