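"""Rule-tree classification of oriented objects into four classes.

Class 1: straight individual chromosome.
Class 2: skewed/bent individual chromosome.
Class 3: touching or overlapping chromosomes.
Class 4: non-chromosome residue (small, large or short subtype).

The tree first gates on the fill ratio of the enclosing rectangle: well
filled objects are straight candidates and are accepted as Class 1 when
their rectangle-width ratio lies inside a band around 1, otherwise they
are small or large residues.  Poorly filled objects are residues when
their height ratio is low, overlapping clusters when their maximum-width
ratio is high, and skewed individuals otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .features import ObjectFeatures

__all__ = ["RuleThresholds", "ClassLabel", "classify_object", "classify_spread", "load_thresholds"]

#: Valid values for the ambiguous-branch switch: which feature is compared
#: against ``area_gate`` to choose between the straight and skewed branches.
BRANCH_FEATURES = ("area_ratio", "wrect_ratio")


@dataclass(frozen=True)
class RuleThresholds:
    """The decision constants of the classifier.

    Fractions are stored as fractions (0.6784), never percentages.
    """

    area_gate: float = 0.6784
    wrect_lo: float = 0.9897
    wrect_hi: float = 1.5597
    hi_min: float = 0.7507
    wmax_gate: float = 2.3453
    discard_factor: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 < self.area_gate < 1.0:
            raise ValueError("area_gate must be in (0, 1)")
        if not 0.0 < self.wrect_lo < self.wrect_hi:
            raise ValueError("need 0 < wrect_lo < wrect_hi")
        if self.hi_min <= 0.0:
            raise ValueError("hi_min must be > 0")
        if self.wmax_gate <= 1.0:
            raise ValueError("wmax_gate must be > 1")
        if self.discard_factor <= 1.0:
            raise ValueError("discard_factor must be > 1")


@dataclass(frozen=True)
class ClassLabel:
    """Class value in {1, 2, 3, 4}; Class-4 labels carry a subtype tag."""

    value: int
    subtype: str | None = None

    def __post_init__(self) -> None:
        if self.value not in (1, 2, 3, 4):
            raise ValueError("class value must be 1..4")
        if (self.value == 4) != (self.subtype is not None):
            raise ValueError("subtype present iff value == 4")


def classify_object(
    f: ObjectFeatures,
    t: RuleThresholds | None = None,
    branch_feature: str = "area_ratio",
) -> ClassLabel:
    """Apply the decision tree to one completed feature vector.

    ``branch_feature`` selects which feature is gated to split the straight
    branch from the skewed/overlap branch; ``"area_ratio"`` is the default
    (and the consistent reading of the rule), ``"wrect_ratio"`` is offered
    as an explicit alternative interpretation.
    """
    if t is None:
        t = RuleThresholds()
    if not f.complete:
        raise ValueError("features incomplete: relative ratios missing")
    if branch_feature not in BRANCH_FEATURES:
        raise ValueError(f"branch_feature must be one of {BRANCH_FEATURES}")

    gate_value = f.area_ratio if branch_feature == "area_ratio" else f.wrect_ratio
    if gate_value > t.area_gate:
        if f.wrect_ratio < t.wrect_lo:
            return ClassLabel(4, "small_residue")
        if f.wrect_ratio > t.wrect_hi:
            return ClassLabel(4, "large_residue")
        return ClassLabel(1)
    if f.hi_ratio < t.hi_min:
        return ClassLabel(4, "short_residue")
    if f.wmax_ratio > t.wmax_gate:
        return ClassLabel(3)
    return ClassLabel(2)


def classify_spread(
    objects: list[ObjectFeatures],
    t: RuleThresholds | None = None,
    branch_feature: str = "area_ratio",
) -> list[tuple[int, ClassLabel]]:
    """Classify every object of one image; order is preserved."""
    return [
        (f.object_id, classify_object(f, t, branch_feature)) for f in objects
    ]


def load_thresholds(path: str | Path) -> tuple[RuleThresholds, dict[str, str]]:
    """Read a ``key = value`` config file overriding the default thresholds.

    Recognized keys are exactly the :class:`RuleThresholds` field names;
    lines starting with ``#`` are comments.  Unrecognized keys are returned
    untouched in a second dict (the CLI uses ``branch_feature`` and
    ``class3_tiebreak`` from there).
    """
    fields = {f for f in RuleThresholds.__dataclass_fields__}
    overrides: dict[str, float] = {}
    extras: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key in fields:
            overrides[key] = float(value)
        else:
            extras[key] = value
    return RuleThresholds(**overrides), extras
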