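"""Run configuration: TOML schema plus a CSV template importer.

Paths inside a config file are resolved relative to the file itself, so an
input tree can be moved as a unit.  Every default that fills an omitted key
is logged, and unknown keys are rejected in strict mode.
"""

from __future__ import annotations

import csv
import logging
import tomllib
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any

from .atlas_io import DEFAULT_SECTION_PATTERN
from .errors import ConfigError
from .transform import ScaleSpec

logger = logging.getLogger(__name__)

_MANDATORY = (
    "segmentation_dir", "atlas_dir", "anchoring", "label_table",
    "output_dir", "base_pixel_size",
)
_PATH_KEYS = (
    "segmentation_dir", "atlas_dir", "anchoring", "label_table",
    "output_dir", "custom_regions",
)


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters for one quantification run."""

    segmentation_dir: Path
    atlas_dir: Path
    anchoring: Path
    label_table: Path
    output_dir: Path
    base_pixel_size: float
    resize_factor: float = 1.0
    custom_regions: Path | None = None
    min_px: int = 1
    max_px: int = 10_000_000
    connectivity: int = 8
    attribution: str = "pixel"
    target_colours: tuple[tuple[int, int, int], ...] = ((255, 0, 255),)
    convention: str = "centre"
    atlas_mode: str = "colour"
    section_pattern: str = DEFAULT_SECTION_PATTERN
    export_granularity: str = "pixel"
    export_subsample: int = 1
    atlas_alpha: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.base_pixel_size > 0:
            raise ConfigError(f"base_pixel_size must be positive, got {self.base_pixel_size}")
        if not 0 < self.resize_factor <= 1:
            raise ConfigError(f"resize_factor must be in (0, 1], got {self.resize_factor}")
        if not 1 <= self.min_px <= self.max_px:
            raise ConfigError(
                f"size bounds must satisfy 1 <= min_px <= max_px, "
                f"got [{self.min_px}, {self.max_px}]"
            )
        if self.connectivity not in (4, 8):
            raise ConfigError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if self.attribution not in ("pixel", "anchor"):
            raise ConfigError(f"attribution must be 'pixel' or 'anchor', got {self.attribution!r}")
        if self.convention not in ("centre", "corner"):
            raise ConfigError(f"convention must be 'centre' or 'corner', got {self.convention!r}")
        if self.atlas_mode not in ("colour", "raw"):
            raise ConfigError(f"atlas_mode must be 'colour' or 'raw', got {self.atlas_mode!r}")
        if self.export_granularity not in ("pixel", "centroid"):
            raise ConfigError(
                f"export_granularity must be 'pixel' or 'centroid', "
                f"got {self.export_granularity!r}"
            )
        if self.export_subsample < 1:
            raise ConfigError(f"export_subsample must be >= 1, got {self.export_subsample}")
        if not 0.0 <= self.atlas_alpha <= 1.0:
            raise ConfigError(f"atlas_alpha must be in [0, 1], got {self.atlas_alpha}")
        for colour in self.target_colours:
            if len(colour) != 3 or any(not 0 <= int(c) <= 255 for c in colour):
                raise ConfigError(f"bad target colour {colour}")
        if not self.target_colours:
            raise ConfigError("at least one target colour is required")

    @property
    def scale(self) -> ScaleSpec:
        return ScaleSpec(self.base_pixel_size, self.resize_factor)

    def validate_paths(self) -> None:
        for key in ("segmentation_dir", "atlas_dir", "anchoring",
                    "label_table", "custom_regions"):
            value = getattr(self, key)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"{key} does not exist: {value}")

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for f in fields(self):
            value = getattr(self, f.name)
            if isinstance(value, Path):
                value = str(value)
            elif f.name == "target_colours":
                value = [list(c) for c in value]
            out[f.name] = value
        return out


_KNOWN_KEYS = {f.name for f in fields(RunConfig)}


def _coerce_csv_value(key: str, raw: str) -> Any:
    if key in ("base_pixel_size", "resize_factor", "atlas_alpha"):
        return float(raw)
    if key in ("min_px", "max_px", "connectivity", "seed", "export_subsample"):
        return int(raw)
    if key == "target_colours":
        colours = []
        for part in raw.split("|"):
            comps = [int(c) for c in part.split(";")]
            colours.append(comps)
        return colours
    return raw


def _build(raw: dict[str, Any], base: Path, strict: bool) -> RunConfig:
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        message = f"unknown config keys: {sorted(unknown)}"
        if strict:
            raise ConfigError(message)
        logger.warning("%s (ignored; strict mode off)", message)
        raw = {k: v for k, v in raw.items() if k in _KNOWN_KEYS}
    missing = [k for k in _MANDATORY if k not in raw]
    if missing:
        raise ConfigError(f"missing mandatory config keys: {missing}")
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in _PATH_KEYS and value is not None:
            value = (base / value).resolve() if not Path(value).is_absolute() else Path(value)
        if key == "target_colours":
            value = tuple(tuple(int(c) for c in colour) for colour in value)
        kwargs[key] = value
    for f in fields(RunConfig):
        if f.name not in kwargs and f.name not in _MANDATORY:
            logger.info("config: %s defaulted to %r", f.name, f.default)
    return RunConfig(**kwargs)


def load_config(path: str | Path, strict: bool = True) -> RunConfig:
    """Load a run configuration from TOML, or from the CSV template rendering
    (rows of ``key,value``) when the file ends in ``.csv``."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file does not exist: {path}")
    base = path.parent
    if path.suffix.lower() == ".csv":
        raw: dict[str, Any] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for lineno, row in enumerate(csv.reader(fh), start=1):
                if not row or not row[0].strip() or row[0].strip() == "key":
                    continue
                key = row[0].strip()
                if len(row) < 2:
                    raise ConfigError(f"{path}: row {lineno}: missing value for {key!r}")
                try:
                    raw[key] = _coerce_csv_value(key, row[1].strip())
                except ValueError as exc:
                    raise ConfigError(f"{path}: row {lineno}: {exc}") from exc
    else:
        try:
            raw = tomllib.loads(path.read_text(encoding="utf-8"))
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
    return _build(raw, base, strict)
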