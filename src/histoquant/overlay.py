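"""Report images: objects colour-coded by region over the atlas map."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw

from .atlas_io import AtlasMap, LabelTable
from .errors import ParameterError
from .objects import ExtractedObject


@dataclass(frozen=True)
class OverlayStyle:
    """Rendering options.

    ``atlas_alpha`` blends region colours over white; ``boundary_colour``
    is optional — when ``None`` no region boundaries are drawn (so with
    alpha 1 and no objects the overlay is exactly the re-encoded atlas).
    """

    atlas_alpha: float = 1.0
    object_colour_mode: str = "by-region"  # or "fixed"
    fixed_colour: tuple[int, int, int] = (0, 0, 0)
    boundary_colour: tuple[int, int, int] | None = None
    draw_labels: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.atlas_alpha <= 1.0:
            raise ParameterError(f"atlas_alpha must be in [0, 1], got {self.atlas_alpha}")
        if self.object_colour_mode not in ("by-region", "fixed"):
            raise ParameterError(
                f"object_colour_mode must be 'by-region' or 'fixed', "
                f"got {self.object_colour_mode!r}"
            )


def boundary_mask(amap: AtlasMap) -> np.ndarray:
    """One-pixel-wide boundary set: pixels whose label differs from the
    4-neighbour to the right or below."""
    lab = amap.labels
    mask = np.zeros(lab.shape, dtype=bool)
    mask[:, :-1] |= lab[:, :-1] != lab[:, 1:]
    mask[:-1, :] |= lab[:-1, :] != lab[1:, :]
    return mask


def render_overlay(
    amap: AtlasMap,
    objects: list[ExtractedObject],
    table: LabelTable,
    style: OverlayStyle = OverlayStyle(),
) -> np.ndarray:
    """Deterministic RGB rendering at the map's dimensions.

    Layers, back to front: atlas colours blended over white at
    ``atlas_alpha``; optional region boundaries; object pixels in their
    assigned region's colour (or a fixed colour); optional acronym labels.
    """
    palette = np.zeros((max(table.ids) + 1, 3), dtype=np.float64)
    for rec in table:
        palette[rec.region_id] = rec.colour
    img = palette[amap.labels]
    img = style.atlas_alpha * img + (1.0 - style.atlas_alpha) * 255.0
    img = np.rint(img).astype(np.uint8)
    if style.boundary_colour is not None:
        img[boundary_mask(amap)] = style.boundary_colour
    for obj in objects:
        if style.object_colour_mode == "by-region" and obj.region_id is not None:
            colour = table.by_id(obj.region_id).colour
        else:
            colour = style.fixed_colour
        for x, y in obj.pixels:
            img[y, x] = colour
    if style.draw_labels:
        img = _draw_labels(img, amap, table)
    return img


def _draw_labels(img: np.ndarray, amap: AtlasMap, table: LabelTable) -> np.ndarray:
    pil = Image.fromarray(img)
    draw = ImageDraw.Draw(pil)
    for rec in table:
        if rec.region_id == table.background_id:
            continue
        ys, xs = np.nonzero(amap.labels == rec.region_id)
        if xs.size == 0:
            continue
        draw.text((float(xs.mean()), float(ys.mean())), rec.acronym, fill=(0, 0, 0))
    return np.asarray(pil)
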