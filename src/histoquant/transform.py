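"""Image-series pre-processing and pixel/physical-unit arithmetic.

Covers lossless re-orientation (quarter-turn rotation, mirroring), series
renaming, resolution changes, and the conversion between pixel counts and
physical areas that every downstream report depends on.
"""

from __future__ import annotations

import logging
import math
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image

from .errors import CollisionError, ParameterError, SizeError, TemplateError

logger = logging.getLogger(__name__)

#: Resampling kernels accepted by :func:`resize_image`.
RESAMPLE_METHODS = ("nearest", "area")


@dataclass(frozen=True)
class ScaleSpec:
    """Physical scale of a segmentation image.

    Parameters
    ----------
    base_pixel_size:
        Micrometres per pixel in the originally scanned image.
    resize_factor:
        Downscaling factor applied before segmentation, in ``(0, 1]``.
    """

    base_pixel_size: float
    resize_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.base_pixel_size > 0:
            raise ParameterError(
                f"base_pixel_size must be positive, got {self.base_pixel_size}"
            )
        if not 0 < self.resize_factor <= 1:
            raise ParameterError(
                f"resize_factor must be in (0, 1], got {self.resize_factor}"
            )

    @property
    def um_per_px(self) -> float:
        """Micrometres spanned by one segmentation pixel (one side)."""
        return self.base_pixel_size / self.resize_factor


def pixel_area_um2(scale: ScaleSpec) -> float:
    """Area in square micrometres represented by one segmentation pixel."""
    return scale.um_per_px ** 2


def object_area_um2(n_pixels: int, scale: ScaleSpec) -> float:
    """Physical area of an object made of ``n_pixels`` segmentation pixels."""
    if n_pixels < 0:
        raise ParameterError(f"n_pixels must be >= 0, got {n_pixels}")
    return n_pixels * pixel_area_um2(scale)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _nearest_indices(n_out: int, n_in: int) -> np.ndarray:
    # pixel-centre mapping; identity when n_out == n_in
    idx = np.floor((np.arange(n_out) + 0.5) * (n_in / n_out)).astype(np.intp)
    return np.clip(idx, 0, n_in - 1)


def resize_image(image: np.ndarray, factor: float, method: str = "nearest") -> np.ndarray:
    """Resize an image by ``factor``.

    Output dimensions are round-half-up of ``factor * dimension``.  ``method``
    selects the kernel: ``"nearest"`` for label-like content (bit-identical at
    factor 1.0), ``"area"`` for photographic content.
    """
    if not 0 < factor <= 1:
        raise ParameterError(f"resize factor must be in (0, 1], got {factor}")
    if method not in RESAMPLE_METHODS:
        raise ParameterError(f"unknown resample method {method!r}")
    image = np.asarray(image)
    h, w = image.shape[:2]
    out_w = _round_half_up(factor * w)
    out_h = _round_half_up(factor * h)
    if out_w < 1 or out_h < 1:
        raise SizeError(
            f"factor {factor} collapses {w}x{h} image to {out_w}x{out_h}"
        )
    logger.debug("resize %dx%d -> %dx%d (%s)", w, h, out_w, out_h, method)
    if method == "nearest":
        ys = _nearest_indices(out_h, h)
        xs = _nearest_indices(out_w, w)
        return np.ascontiguousarray(image[np.ix_(ys, xs)])
    pil = Image.fromarray(image)
    return np.asarray(pil.resize((out_w, out_h), Image.BOX))


def rotate_image(image: np.ndarray, quarter_turns: int) -> np.ndarray:
    """Rotate by ``quarter_turns`` clockwise quarter turns (0-3), losslessly."""
    if quarter_turns not in (0, 1, 2, 3):
        raise ParameterError(f"quarter_turns must be in 0..3, got {quarter_turns}")
    return np.ascontiguousarray(np.rot90(np.asarray(image), k=-quarter_turns))


def mirror_image(image: np.ndarray, axis: str) -> np.ndarray:
    """Mirror an image: ``"horizontal"`` flips left/right, ``"vertical"`` top/bottom."""
    image = np.asarray(image)
    if axis == "horizontal":
        return np.ascontiguousarray(image[:, ::-1])
    if axis == "vertical":
        return np.ascontiguousarray(image[::-1])
    raise ParameterError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")


def rename_series(
    filenames: Sequence[str],
    template: str,
    start: int = 1,
    step: int = 1,
) -> dict[str, str]:
    """Compute an injective old-name -> new-name mapping for a section series.

    ``template`` must contain exactly one ``{N}`` placeholder (format specs
    such as ``{N:03}`` are allowed).  No filesystem side effects: callers apply
    the returned mapping themselves, so validation always precedes mutation.
    """
    fields = [f for _, f, _, _ in string.Formatter().parse(template) if f is not None]
    if fields != ["N"]:
        raise TemplateError(
            f"template must contain exactly one {{N}} placeholder, got {template!r}"
        )
    mapping: dict[str, str] = {}
    for i, old in enumerate(filenames):
        mapping[str(old)] = template.format(N=start + i * step)
    if len(set(mapping.values())) != len(mapping):
        seen: dict[str, str] = {}
        for old, new in mapping.items():
            if new in seen:
                raise CollisionError(
                    f"{seen[new]!r} and {old!r} both map to {new!r}"
                )
            seen[new] = old
    return mapping


def transform_directory(
    input_dir: str | Path,
    output_dir: str | Path,
    *,
    resize: float | None = None,
    resample: str = "nearest",
    rotate: int = 0,
    mirror: str | None = None,
    rename_template: str | None = None,
    start: int = 1,
    step: int = 1,
    dry_run: bool = False,
) -> Mapping[str, str]:
    """Apply a transform pipeline to every PNG/TIFF in ``input_dir``.

    Returns the old->new filename mapping.  With ``dry_run`` the mapping is
    computed and validated but nothing is read or written.
    """
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    names = sorted(
        p.name for p in input_dir.iterdir()
        if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if rename_template is not None:
        mapping = rename_series(names, rename_template, start=start, step=step)
    else:
        mapping = {n: str(Path(n).with_suffix(".png")) for n in names}
        if len(set(mapping.values())) != len(mapping):
            raise CollisionError("suffix normalisation collides; use --rename-template")
    if dry_run:
        for old, new in mapping.items():
            logger.info("dry-run: %s -> %s", old, new)
        return mapping
    output_dir.mkdir(parents=True, exist_ok=True)
    for old, new in mapping.items():
        img = np.asarray(Image.open(input_dir / old).convert("RGB"))
        if rotate:
            img = rotate_image(img, rotate)
        if mirror is not None:
            img = mirror_image(img, mirror)
        if resize is not None:
            img = resize_image(img, resize, method=resample)
        Image.fromarray(img).save(output_dir / new)
        logger.info("wrote %s (resample=%s)", new, resample)
    return mapping
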