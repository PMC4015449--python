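"""End-to-end processing of a single gray image.

Glue between the stage modules: equalize -> segment -> orient -> features
-> classify.  The classification path is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import classify as _classify
from . import features as _features
from . import imaging as _imaging

__all__ = ["ObjectResult", "ImageResult", "process_array"]


@dataclass(frozen=True)
class ObjectResult:
    seg: _imaging.SegmentedObject
    oriented: _imaging.OrientedObject
    features: _features.ObjectFeatures
    label: _classify.ClassLabel


@dataclass(frozen=True)
class ImageResult:
    objects: list[ObjectResult]
    stats: _features.ImageWidthStats | None

    @property
    def labels(self) -> list[_classify.ClassLabel]:
        return [o.label for o in self.objects]


def process_array(
    gray: np.ndarray,
    thresholds: _classify.RuleThresholds | None = None,
    min_object_px: int = 20,
    branch_feature: str = "area_ratio",
    equalize: bool = True,
) -> ImageResult:
    """Run the full classification pipeline on a gray image array."""
    if thresholds is None:
        thresholds = _classify.RuleThresholds()
    img = _imaging.equalize(gray) if equalize else np.asarray(gray)
    segs = _imaging.segment(img, min_object_px=min_object_px)
    if not segs:
        return ImageResult(objects=[], stats=None)
    oriented = [_imaging.orient_vertical(s) for s in segs]
    partial = [_features.basic_features(o) for o in oriented]
    stats = _features.width_stats(
        partial, gate=thresholds.area_gate,
        discard_factor=thresholds.discard_factor,
    )
    complete = [_features.relative_features(f, stats) for f in partial]
    labels = _classify.classify_spread(complete, thresholds, branch_feature)
    return ImageResult(
        objects=[
            ObjectResult(seg=s, oriented=o, features=f, label=lab)
            for s, o, f, (_, lab) in zip(segs, oriented, complete, labels)
        ],
        stats=stats,
    )
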