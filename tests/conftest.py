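import numpy as np
import pytest

from histoquant.atlas_io import AtlasMap, LabelTable, RegionRecord, SectionAnchor


@pytest.fixture
def table() -> LabelTable:
    return LabelTable(
        [
            RegionRecord(0, "background", "bg", (0, 0, 0), None),
            RegionRecord(1, "Isocortex", "Cx", (255, 0, 0), 0),
            RegionRecord(2, "HPF", "HPF", (0, 255, 0), 0),
            RegionRecord(3, "Olf", "Olf", (0, 0, 255), 0),
            RegionRecord(5, "Thal", "Th", (255, 255, 0), 0),
            RegionRecord(6, "Hyp", "Hy", (0, 255, 255), 0),
        ]
    )


@pytest.fixture
def anchor() -> SectionAnchor:
    return SectionAnchor(
        "img_s001.png", 10, 10,
        o=(0.0, 0.0, 0.0), u=(10.0, 0.0, 0.0), v=(0.0, 0.0, 10.0),
    )


def make_map(labels) -> AtlasMap:
    return AtlasMap(np.asarray(labels, dtype=np.int64))


def mask_image(member: np.ndarray, colour=(255, 0, 255)) -> np.ndarray:
    """RGB image that is white except ``colour`` where ``member`` is true."""
    img = np.full(member.shape + (3,), 255, dtype=np.uint8)
    img[np.asarray(member, bool)] = colour
    return img


def assert_same_partition(objects, oracle_labels: np.ndarray) -> None:
    """Objects and an oracle label image induce the same pixel partition."""
    mine = np.zeros_like(oracle_labels)
    for obj in objects:
        for x, y in obj.pixels:
            mine[y, x] = obj.object_id
    assert np.array_equal(mine > 0, oracle_labels > 0), "membership differs"
    if not (mine > 0).any():
        return
    pairs = np.stack([mine[mine > 0], oracle_labels[mine > 0]])
    uniq = np.unique(pairs, axis=1)
    n_pairs = uniq.shape[1]
    assert len(np.unique(uniq[0])) == n_pairs, "one object spans two oracle components"
    assert len(np.unique(uniq[1])) == n_pairs, "one oracle component split in two"
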