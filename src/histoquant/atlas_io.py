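"""Reading, validating and matching atlas-side inputs.

A quantification run joins three kinds of files on a shared section key:
colour segmentation images, section-matched atlas label maps, and an
anchoring file that places each section plane in 3D atlas space via the
``o``/``u``/``v`` vectors.  This module owns the file dialects and the join.
"""

from __future__ import annotations

import csv
import json
import re
import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from PIL import Image

from .errors import DecodeError, FormatError, HierarchyError, NamingError, ParameterError

LABEL_TABLE_COLUMNS = ("id", "name", "acronym", "red", "green", "blue", "parent_id")
ANCHOR_VECTOR_KEYS = ("ox", "oy", "oz", "ux", "uy", "uz", "vx", "vy", "vz")
DEFAULT_SECTION_PATTERN = r"_s(\d+)"
_QMAP_MAGIC = b"QMAP"


@dataclass(frozen=True)
class RegionRecord:
    """One row of the region label table."""

    region_id: int
    name: str
    acronym: str
    colour: tuple[int, int, int]
    parent_id: int | None


class LabelTable:
    """Validated, ordered collection of :class:`RegionRecord`.

    Lookup is total by id and by colour; parent links are checked for cycles
    and dangling references at construction time.
    """

    def __init__(self, records: Sequence[RegionRecord], background_id: int = 0):
        self.records: tuple[RegionRecord, ...] = tuple(records)
        self.background_id = background_id
        self._by_id: dict[int, RegionRecord] = {}
        self._by_colour: dict[tuple[int, int, int], RegionRecord] = {}
        for rec in self.records:
            if rec.region_id < 0:
                raise FormatError(f"negative region id {rec.region_id}")
            if rec.region_id in self._by_id:
                raise FormatError(f"duplicate region id {rec.region_id}")
            if rec.colour in self._by_colour:
                raise FormatError(
                    f"duplicate colour {rec.colour} (ids "
                    f"{self._by_colour[rec.colour].region_id} and {rec.region_id})"
                )
            self._by_id[rec.region_id] = rec
            self._by_colour[rec.colour] = rec
        if background_id not in self._by_id:
            raise FormatError(f"background id {background_id} missing from table")
        self._check_hierarchy()

    def _check_hierarchy(self) -> None:
        for rec in self.records:
            seen = {rec.region_id}
            cur = rec.parent_id
            while cur is not None:
                if cur in seen:
                    raise HierarchyError(
                        f"cyclic parent chain through region {rec.region_id}"
                    )
                if cur not in self._by_id:
                    raise HierarchyError(
                        f"region {rec.region_id} has unknown parent {cur}"
                    )
                seen.add(cur)
                cur = self._by_id[cur].parent_id

    # -- lookup ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[RegionRecord]:
        return iter(self.records)

    def __contains__(self, region_id: int) -> bool:
        return region_id in self._by_id

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(r.region_id for r in self.records)

    def by_id(self, region_id: int) -> RegionRecord:
        return self._by_id[region_id]

    def by_colour(self, colour: tuple[int, int, int]) -> RegionRecord:
        return self._by_colour[tuple(colour)]

    def children(self, region_id: int) -> tuple[int, ...]:
        return tuple(
            r.region_id for r in self.records if r.parent_id == region_id
        )

    def descendants(self, region_id: int, include_self: bool = False) -> set[int]:
        """All ids below ``region_id`` in the parent hierarchy."""
        if region_id not in self._by_id:
            raise KeyError(region_id)
        out: set[int] = {region_id} if include_self else set()
        stack = list(self.children(region_id))
        while stack:
            rid = stack.pop()
            if rid not in out:
                out.add(rid)
                stack.extend(self.children(rid))
        return out

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(LABEL_TABLE_COLUMNS)
            for r in self.records:
                writer.writerow(
                    [
                        r.region_id, r.name, r.acronym,
                        r.colour[0], r.colour[1], r.colour[2],
                        "" if r.parent_id is None else r.parent_id,
                    ]
                )


def _unused_grey(taken: Iterable[tuple[int, int, int]]) -> tuple[int, int, int]:
    taken = set(taken)
    for v in range(256):
        if (v, v, v) not in taken:
            return (v, v, v)
    raise FormatError("no free colour left for the background row")


def load_label_table(path: str | Path, background_id: int = 0) -> LabelTable:
    """Load a region table from CSV (``id,name,acronym,red,green,blue,parent_id``).

    A background row is auto-added (with an unused grey colour) if the table
    does not provide one.
    """
    records: list[RegionRecord] = []
    seen_ids: dict[int, int] = {}
    seen_colours: dict[tuple[int, int, int], int] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) != set(LABEL_TABLE_COLUMNS):
            raise FormatError(
                f"{path}: header must be {','.join(LABEL_TABLE_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                rid = int(row["id"])
                colour = (int(row["red"]), int(row["green"]), int(row["blue"]))
                parent_raw = (row["parent_id"] or "").strip()
                parent = None if parent_raw in ("", "none", "None") else int(parent_raw)
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}: row {lineno}: {exc}") from exc
            if any(not 0 <= c <= 255 for c in colour):
                raise FormatError(f"{path}: row {lineno}: colour {colour} out of range")
            if rid in seen_ids:
                raise FormatError(
                    f"{path}: row {lineno}: duplicate id {rid} (first at row {seen_ids[rid]})"
                )
            if colour in seen_colours:
                raise FormatError(
                    f"{path}: row {lineno}: duplicate colour {colour} "
                    f"(first at row {seen_colours[colour]})"
                )
            seen_ids[rid] = lineno
            seen_colours[colour] = lineno
            records.append(RegionRecord(rid, row["name"], row["acronym"], colour, parent))
    if background_id not in seen_ids:
        records.insert(
            0,
            RegionRecord(background_id, "background", "bg",
                         _unused_grey(seen_colours), None),
        )
    return LabelTable(records, background_id=background_id)


# ---------------------------------------------------------------------------
# atlas maps


@dataclass(frozen=True)
class AtlasMap:
    """Per-pixel region-label grid matched to one section image."""

    labels: np.ndarray  # (height, width) integer grid

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise FormatError(f"label grid must be 2-D, got shape {self.labels.shape}")

    @property
    def width(self) -> int:
        return int(self.labels.shape[1])

    @property
    def height(self) -> int:
        return int(self.labels.shape[0])


def _pack_colour(colour: tuple[int, int, int]) -> int:
    return (colour[0] << 16) | (colour[1] << 8) | colour[2]


def load_atlas_map(path: str | Path, table: LabelTable, mode: str = "colour") -> AtlasMap:
    """Decode an atlas map file against ``table``.

    ``mode="colour"``: 24-bit PNG whose palette is exactly the table colours
    (no nearest-colour snapping — an off-palette pixel is an error).
    ``mode="raw"``: the QMAP little-endian label-matrix dialect.
    """
    if mode == "colour":
        return _load_atlas_map_colour(path, table)
    if mode == "raw":
        return _load_atlas_map_raw(path, table)
    raise ParameterError(f"mode must be 'colour' or 'raw', got {mode!r}")


def _load_atlas_map_colour(path: str | Path, table: LabelTable) -> AtlasMap:
    img = Image.open(path)
    if img.mode != "RGB":
        img = img.convert("RGB")
    arr = np.asarray(img, dtype=np.uint32)
    packed = (arr[..., 0] << 16) | (arr[..., 1] << 8) | arr[..., 2]
    colour_to_id = {_pack_colour(r.colour): r.region_id for r in table}
    uniq, inverse = np.unique(packed, return_inverse=True)
    ids = np.empty(uniq.shape, dtype=np.int64)
    for i, code in enumerate(uniq):
        code = int(code)
        if code not in colour_to_id:
            flat = np.flatnonzero(packed.ravel() == code)[0]
            y, x = divmod(int(flat), packed.shape[1])
            colour = ((code >> 16) & 255, (code >> 8) & 255, code & 255)
            raise DecodeError(
                f"{path}: colour {colour} at pixel ({x}, {y}) not in label table"
            )
        ids[i] = colour_to_id[code]
    return AtlasMap(ids[inverse].reshape(packed.shape))


def _load_atlas_map_raw(path: str | Path, table: LabelTable) -> AtlasMap:
    data = Path(path).read_bytes()
    if len(data) < 12 or data[:4] != _QMAP_MAGIC:
        raise FormatError(f"{path}: not a QMAP file")
    width, height = struct.unpack_from("<II", data, 4)
    expected = 12 + 4 * width * height
    if len(data) != expected:
        raise FormatError(
            f"{path}: size header says {width}x{height} "
            f"({expected} bytes) but file has {len(data)} bytes"
        )
    labels = np.frombuffer(data, dtype="<u4", offset=12).astype(np.int64)
    unknown = set(np.unique(labels).tolist()) - set(table.ids)
    if unknown:
        raise DecodeError(f"{path}: region ids {sorted(unknown)} not in label table")
    return AtlasMap(labels.reshape(height, width))


def write_atlas_map(
    amap: AtlasMap,
    path: str | Path,
    table: LabelTable | None = None,
    mode: str = "colour",
) -> None:
    """Encode an atlas map to disk (inverse of :func:`load_atlas_map`)."""
    if mode == "colour":
        if table is None:
            raise ParameterError("colour mode requires a label table")
        palette = np.zeros((max(table.ids) + 1, 3), dtype=np.uint8)
        for rec in table:
            palette[rec.region_id] = rec.colour
        Image.fromarray(palette[amap.labels]).save(path, format="PNG")
    elif mode == "raw":
        header = _QMAP_MAGIC + struct.pack("<II", amap.width, amap.height)
        Path(path).write_bytes(header + amap.labels.astype("<u4").tobytes())
    else:
        raise ParameterError(f"mode must be 'colour' or 'raw', got {mode!r}")


def rescale_atlas_map(amap: AtlasMap, width: int, height: int) -> AtlasMap:
    """Nearest-neighbour resample to ``width`` x ``height``.

    Labels are categorical, so the output pixel takes the label under its
    centre in the input grid; no interpolation, no new labels.
    """
    if width < 1 or height < 1:
        raise ParameterError(f"target dimensions must be positive, got {width}x{height}")
    xs = np.clip(
        np.floor((np.arange(width) + 0.5) * (amap.width / width)).astype(np.intp),
        0, amap.width - 1,
    )
    ys = np.clip(
        np.floor((np.arange(height) + 0.5) * (amap.height / height)).astype(np.intp),
        0, amap.height - 1,
    )
    return AtlasMap(np.ascontiguousarray(amap.labels[np.ix_(ys, xs)]))


# ---------------------------------------------------------------------------
# anchoring


@dataclass(frozen=True)
class SectionAnchor:
    """Plane of one section in atlas space: origin ``o`` plus in-plane ``u``, ``v``."""

    section_key: str
    width: int
    height: int
    o: tuple[float, float, float]
    u: tuple[float, float, float]
    v: tuple[float, float, float]

    def __post_init__(self) -> None:
        # normalise numpy scalars so equality and serialisation are exact
        object.__setattr__(self, "width", int(self.width))
        object.__setattr__(self, "height", int(self.height))
        for name in ("o", "u", "v"):
            object.__setattr__(
                self, name, tuple(float(c) for c in getattr(self, name))
            )
        if self.width <= 0 or self.height <= 0:
            raise FormatError(
                f"slice {self.section_key}: non-positive dimensions "
                f"{self.width}x{self.height}"
            )
        if not any(self.u) and not any(self.v):
            raise FormatError(f"slice {self.section_key}: u and v both zero")


def _anchor_from_record(rec: dict, label: str) -> SectionAnchor:
    for key in ("filename", "width", "height") + ANCHOR_VECTOR_KEYS:
        if key not in rec or rec[key] in (None, ""):
            raise FormatError(f"slice {label}: missing {key!r}")
    vals = {k: float(rec[k]) for k in ANCHOR_VECTOR_KEYS}
    return SectionAnchor(
        section_key=str(rec["filename"]),
        width=int(float(rec["width"])),
        height=int(float(rec["height"])),
        o=(vals["ox"], vals["oy"], vals["oz"]),
        u=(vals["ux"], vals["uy"], vals["uz"]),
        v=(vals["vx"], vals["vy"], vals["vz"]),
    )


def parse_anchoring(path: str | Path) -> list[SectionAnchor]:
    """Parse an anchoring file (XML ``<series><slice .../></series>`` or the
    equivalent JSON list of objects) into one anchor per slice."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(raw, list):
            raise FormatError(f"{path}: JSON anchoring must be a list of objects")
        recs = [(dict(r), str(r.get("filename", f"#{i}"))) for i, r in enumerate(raw)]
    else:
        try:
            root = ET.parse(path).getroot()
        except ET.ParseError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        recs = [
            (dict(el.attrib), el.attrib.get("filename", f"#{i}"))
            for i, el in enumerate(root.iter("slice"))
        ]
    anchors: list[SectionAnchor] = []
    seen: set[str] = set()
    for rec, label in recs:
        anchor = _anchor_from_record(rec, label)
        if anchor.section_key in seen:
            raise FormatError(f"duplicate section key {anchor.section_key!r}")
        seen.add(anchor.section_key)
        anchors.append(anchor)
    return anchors


def serialize_anchoring(
    anchors: Sequence[SectionAnchor], path: str | Path
) -> None:
    """Write anchors back out; format chosen by extension (.xml or .json).

    Floats are written with ``repr`` so a parse/serialize round trip is exact.
    """
    path = Path(path)
    records = []
    for a in anchors:
        rec = {"filename": a.section_key, "width": a.width, "height": a.height}
        rec.update(zip(ANCHOR_VECTOR_KEYS, (*a.o, *a.u, *a.v)))
        records.append(rec)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(records, indent=1), encoding="utf-8")
        return
    root = ET.Element("series")
    for rec in records:
        ET.SubElement(
            root, "slice", {k: repr(v) if isinstance(v, float) else str(v)
                            for k, v in rec.items()}
        )
    ET.ElementTree(root).write(path, encoding="utf-8", xml_declaration=True)


# ---------------------------------------------------------------------------
# section matching


@dataclass(frozen=True)
class SectionTriple:
    """One matched (image, anchor, map) triple joined on the section number."""

    key: int
    image: str
    anchor: SectionAnchor
    map: str


@dataclass(frozen=True)
class MatchResult:
    triples: tuple[SectionTriple, ...]
    unmatched_images: tuple[str, ...]
    unmatched_anchors: tuple[str, ...]
    unmatched_maps: tuple[str, ...]


def extract_section_key(name: str, pattern: str = DEFAULT_SECTION_PATTERN) -> int | None:
    """Extract the numeric section key embedded in a filename, or ``None``.

    Raises :class:`NamingError` if the pattern matches two distinct numbers.
    """
    matches = re.findall(pattern, Path(str(name)).name)
    keys = {int(m) for m in matches}
    if len(keys) > 1:
        raise NamingError(f"{name}: ambiguous section keys {sorted(keys)}")
    return keys.pop() if keys else None


def _key_items(names: Iterable[str], pattern: str, kind: str):
    keyed: dict[int, str] = {}
    unmatched: list[str] = []
    for name in names:
        key = extract_section_key(name, pattern)
        if key is None:
            unmatched.append(str(name))
        elif key in keyed:
            raise NamingError(
                f"{kind} {keyed[key]!r} and {name!r} both parse to section {key}"
            )
        else:
            keyed[key] = str(name)
    return keyed, unmatched


def match_sections(
    images: Sequence[str],
    anchors: Sequence[SectionAnchor],
    maps: Sequence[str],
    pattern: str = DEFAULT_SECTION_PATTERN,
) -> MatchResult:
    """Join segmentation images, anchors and atlas maps on their section key.

    Items without a full triple are reported, never silently dropped.
    """
    img_by_key, img_loose = _key_items(images, pattern, "image")
    map_by_key, map_loose = _key_items(maps, pattern, "atlas map")
    anchor_by_key: dict[int, SectionAnchor] = {}
    anchor_loose: list[str] = []
    for anchor in anchors:
        key = extract_section_key(anchor.section_key, pattern)
        if key is None:
            anchor_loose.append(anchor.section_key)
        elif key in anchor_by_key:
            raise NamingError(f"two anchors both parse to section {key}")
        else:
            anchor_by_key[key] = anchor
    common = sorted(set(img_by_key) & set(anchor_by_key) & set(map_by_key))
    triples = tuple(
        SectionTriple(k, img_by_key[k], anchor_by_key[k], map_by_key[k])
        for k in common
    )
    return MatchResult(
        triples=triples,
        unmatched_images=tuple(
            sorted(img_loose + [v for k, v in img_by_key.items() if k not in common])
        ),
        unmatched_anchors=tuple(
            sorted(anchor_loose + [a.section_key for k, a in anchor_by_key.items()
                                   if k not in common])
        ),
        unmatched_maps=tuple(
            sorted(map_loose + [v for k, v in map_by_key.items() if k not in common])
        ),
    )
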