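import numpy as np
import pytest

from metasel.features import ObjectFeatures
from metasel.imaging import SegmentedObject


def make_features(
    object_id: int = 1,
    area_ratio: float = 0.8,
    wrect_ratio: float = 1.2,
    hi_ratio: float = 1.0,
    wmax_ratio: float = 1.2,
) -> ObjectFeatures:
    """Feature vector with the four decision ratios set; raw fields nominal."""
    return ObjectFeatures(
        object_id=object_id,
        a_o=320,
        w_rect=8,
        h_rect=40,
        area_ratio=area_ratio,
        w_i=8.0,
        w_max=8,
        wrect_ratio=wrect_ratio,
        h_i=40.0,
        hi_ratio=hi_ratio,
        wmax_ratio=wmax_ratio,
    )


def as_segmented(mask: np.ndarray, object_id: int = 1) -> SegmentedObject:
    """Wrap a tight boolean mask as a SegmentedObject at the origin."""
    mask = np.asarray(mask, dtype=bool)
    return SegmentedObject(
        object_id=object_id,
        mask=mask,
        bbox_origin=(0, 0),
        pixel_count=int(mask.sum()),
    )


def tilted_bar_mask(angle_deg: float, length: float = 60.0,
                    width: float = 6.0, size: int = 121) -> np.ndarray:
    """Solid bar at ``angle_deg`` from the vertical (row) axis, tight-cropped."""
    a = np.deg2rad(angle_deg)
    rr, cc = np.mgrid[0:size, 0:size]
    pr, pc = rr - size // 2, cc - size // 2
    dr, dc = np.cos(a), np.sin(a)
    t = pr * dr + pc * dc
    d = np.hypot(pr - t * dr, pc - t * dc)
    mask = (d <= width / 2) & (np.abs(t) <= length / 2)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
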