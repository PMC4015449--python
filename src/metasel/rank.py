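"""Per-image class summaries and suitability ranking.

Images are ranked by the number of individual chromosomes (Class 1 + 2),
descending.  Ties are broken by more Class-3 objects, then by fewer
Class-4 objects, then lexicographically by image id for determinism.
The Class-3 more-is-better tie-break is deliberate (more touching clusters
mean more chromosomes recoverable by manual editing); ``class3_more_is_better
=False`` flips it for users who prefer cleaner spreads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .classify import ClassLabel
from .features import ImageWidthStats

__all__ = ["SpreadSummary", "summarize", "rank_spreads"]


@dataclass(frozen=True)
class SpreadSummary:
    image_id: str
    n_class1: int
    n_class2: int
    n_class3: int
    n_class4: int
    fallback_used: bool = False
    rank: int | None = None

    @property
    def n_individual(self) -> int:
        return self.n_class1 + self.n_class2

    @property
    def n_total(self) -> int:
        return self.n_class1 + self.n_class2 + self.n_class3 + self.n_class4


def summarize(
    image_id: str,
    labels: list[ClassLabel],
    stats: ImageWidthStats | None = None,
) -> SpreadSummary:
    """Tally class labels of one image into a summary."""
    counts = Counter(label.value for label in labels)
    return SpreadSummary(
        image_id=image_id,
        n_class1=counts.get(1, 0),
        n_class2=counts.get(2, 0),
        n_class3=counts.get(3, 0),
        n_class4=counts.get(4, 0),
        fallback_used=bool(stats.fallback_used) if stats is not None else False,
    )


def rank_spreads(
    summaries: list[SpreadSummary],
    class3_more_is_better: bool = True,
) -> list[SpreadSummary]:
    """Order summaries by karyotyping suitability; ranks are 1-based.

    Sort key: n_individual desc, then n_class3 desc (or asc when
    ``class3_more_is_better`` is False), then n_class4 asc, then image_id.
    """
    if not summaries:
        raise ValueError("no summaries to rank")
    ids = [s.image_id for s in summaries]
    dupes = {i for i, c in Counter(ids).items() if c > 1}
    if dupes:
        raise ValueError(f"duplicate image ids: {sorted(dupes)}")
    c3_sign = -1 if class3_more_is_better else 1
    ordered = sorted(
        summaries,
        key=lambda s: (-s.n_individual, c3_sign * s.n_class3, s.n_class4, s.image_id),
    )
    from dataclasses import replace

    return [replace(s, rank=i) for i, s in enumerate(ordered, start=1)]
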