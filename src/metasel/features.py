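"""Geometric feature extraction from vertically oriented objects.

Per-object quantities (area, enclosing-rectangle dimensions, fill ratio,
row-average and maximum widths) are computed first; image-level width
statistics then normalize them into the dimensionless ratios consumed by
the classifier.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .imaging import OrientedObject

__all__ = ["ObjectFeatures", "ImageWidthStats", "basic_features", "width_stats", "relative_features"]

#: Column order for feature CSV export.
FEATURE_COLUMNS = [
    "object_id",
    "a_o",
    "w_rect",
    "h_rect",
    "area_ratio",
    "w_i",
    "w_max",
    "wrect_ratio",
    "h_i",
    "hi_ratio",
    "wmax_ratio",
]


@dataclass(frozen=True)
class ObjectFeatures:
    """Per-object features of a vertically oriented mask.

    ``a_o`` is the object pixel count; ``w_rect``/``h_rect`` the enclosing
    rectangle; ``area_ratio = a_o / (w_rect * h_rect)``; ``w_i = a_o /
    h_rect`` (row-average width); ``w_max`` the widest row's foreground
    count.  The ratios ``wrect_ratio = w_rect / w_avg``, ``h_i = a_o /
    w_avg``, ``hi_ratio = h_i / h_rect`` and ``wmax_ratio = w_max / w_avg``
    need the image-level average width and are ``None`` until
    :func:`relative_features` fills them.
    """

    object_id: int
    a_o: int
    w_rect: int
    h_rect: int
    area_ratio: float
    w_i: float
    w_max: int
    wrect_ratio: float | None = None
    h_i: float | None = None
    hi_ratio: float | None = None
    wmax_ratio: float | None = None

    @property
    def complete(self) -> bool:
        return None not in (self.wrect_ratio, self.h_i, self.hi_ratio, self.wmax_ratio)


@dataclass(frozen=True)
class ImageWidthStats:
    """Image-level average-width estimate with the wide-object discard step.

    ``straight_candidate_ids`` hold objects whose fill ratio exceeds the
    straightness gate; a preliminary mean of their row-average widths is
    taken, objects wider than ``discard_factor`` times that mean are
    excluded, and ``w_avg`` is the mean width of the surviving set ``o_w``.
    When no object passes the gate, ``w_avg`` falls back to the median
    width of all objects and ``fallback_used`` is set.
    """

    straight_candidate_ids: frozenset[int]
    prelim_avg_width: float | None
    o_w_ids: frozenset[int]
    w_avg: float
    fallback_used: bool


def basic_features(obj: OrientedObject) -> ObjectFeatures:
    """Compute the per-object (image-independent) features."""
    mask = np.asarray(obj.mask, dtype=bool)
    a_o = int(mask.sum())
    if a_o == 0:
        raise ValueError("empty mask")
    h_rect, w_rect = mask.shape
    row_widths = mask.sum(axis=1)
    return ObjectFeatures(
        object_id=obj.object_id,
        a_o=a_o,
        w_rect=int(w_rect),
        h_rect=int(h_rect),
        area_ratio=a_o / (w_rect * h_rect),
        w_i=a_o / h_rect,
        w_max=int(row_widths.max()),
    )


def width_stats(
    features: list[ObjectFeatures],
    gate: float = 0.6784,
    discard_factor: float = 1.5,
) -> ImageWidthStats:
    """Two-pass average chromosome width over straight-gate objects.

    Objects with ``area_ratio > gate`` form the candidate set; a
    preliminary mean of their ``w_i`` is taken; candidates with
    ``w_i <= discard_factor * preliminary mean`` form ``o_w`` and their
    mean ``w_i`` is the final ``w_avg``.
    """
    if not features:
        raise ValueError("empty feature list")
    if not 0.0 < gate < 1.0:
        raise ValueError("gate must be in (0, 1)")
    if discard_factor <= 1.0:
        raise ValueError("discard_factor must be > 1")

    candidates = [f for f in features if f.area_ratio > gate]
    if not candidates:
        w_avg = float(np.median([f.w_i for f in features]))
        return ImageWidthStats(
            straight_candidate_ids=frozenset(),
            prelim_avg_width=None,
            o_w_ids=frozenset(),
            w_avg=w_avg,
            fallback_used=True,
        )
    prelim = float(np.mean([f.w_i for f in candidates]))
    o_w = [f for f in candidates if f.w_i <= discard_factor * prelim]
    # o_w cannot be empty: the minimum w_i is always <= the mean
    w_avg = float(np.mean([f.w_i for f in o_w]))
    return ImageWidthStats(
        straight_candidate_ids=frozenset(f.object_id for f in candidates),
        prelim_avg_width=prelim,
        o_w_ids=frozenset(f.object_id for f in o_w),
        w_avg=w_avg,
        fallback_used=False,
    )


def relative_features(partial: ObjectFeatures, stats: ImageWidthStats) -> ObjectFeatures:
    """Fill the ratios that depend on the image-level average width."""
    if stats.w_avg <= 0:
        raise ValueError("w_avg must be positive")
    h_i = partial.a_o / stats.w_avg
    return dataclasses.replace(
        partial,
        wrect_ratio=partial.w_rect / stats.w_avg,
        h_i=h_i,
        hi_ratio=h_i / partial.h_rect,
        wmax_ratio=partial.w_max / stats.w_avg,
    )
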