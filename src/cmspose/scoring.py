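"""Constant-Murley Scale scoring rules.

The CMS awards 100 points: pain 15 + activities of daily living 20 +
range of motion 40 (four 10-point items: forward elevation, lateral
elevation, external rotation, internal rotation) + strength 25.

Scoring conventions implemented here:

* external rotation — four photographed functional items, 2.5 points each;
  an item counts only when the classifier's predicted class equals the item
  number (class 5 = unable to perform);
* internal rotation — six anatomical hand-reach levels mapped directly to
  the CMS point ladder {0, 2, 4, 6, 8, 10};
* elevations — direct angle measurement banded on the CMS 30-degree ladder;
* strength — per-segment classifier votes combined by per-repetition
  majority (ties to the lower class, conservative for a clinical
  instrument), then the maximum across repetitions; patients unable to
  reach 90 degrees of abduction score 0 regardless of predictions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

ER_ITEM_POINTS = Fraction(5, 2)  # 2.5 points per external-rotation item

#: dynamometer pound-bin boundaries -> strength classes 0-4
STRENGTH_BIN_EDGES = (5.0, 10.0, 15.0, 20.0)

#: strength class -> CMS points: pound-bin midpoints capped at 25.
STRENGTH_POINT_MAPS: dict[str, dict[int, float]] = {
    "midpoint": {0: 2.5, 1: 7.5, 2: 12.5, 3: 17.5, 4: 22.5},
    "class_step": {0: 0.0, 1: 6.25, 2: 12.5, 3: 18.75, 4: 25.0},
}


@dataclass(frozen=True)
class CmsScore:
    """One subject's CMS components and 0-100 total (exact arithmetic)."""

    pain: float
    adl: float
    er: float
    ir: float
    le: float
    fe: float
    strength: float

    def __post_init__(self) -> None:
        ranges = {
            "pain": (self.pain, 15),
            "adl": (self.adl, 20),
            "er": (self.er, 10),
            "ir": (self.ir, 10),
            "le": (self.le, 10),
            "fe": (self.fe, 10),
            "strength": (self.strength, 25),
        }
        for name, (v, hi) in ranges.items():
            if not (0 <= v <= hi):
                raise ValueError(f"{name}={v} outside [0, {hi}]")

    @property
    def total(self) -> float:
        frac = sum(Fraction(str(v)) for v in (
            self.pain, self.adl, self.er, self.ir, self.le, self.fe, self.strength
        ))
        return float(frac)

    def as_dict(self) -> dict[str, float]:
        return {
            "pain": self.pain, "adl": self.adl, "er": self.er, "ir": self.ir,
            "le": self.le, "fe": self.fe, "strength": self.strength, "total": self.total,
        }


def score_external_rotation(item_predictions: Mapping[int, int]) -> float:
    """2.5 points per item whose predicted class equals its item number.

    ``item_predictions`` maps item 1..4 to a predicted class 1..5
    (5 = unable to perform the posture).
    """
    missing = [i for i in (1, 2, 3, 4) if i not in item_predictions]
    if missing:
        raise ValueError(f"missing external-rotation items: {missing}")
    for i in (1, 2, 3, 4):
        if item_predictions[i] not in range(1, 6):
            raise ValueError(f"item {i}: class {item_predictions[i]} outside 1..5")
    correct = sum(1 for i in (1, 2, 3, 4) if item_predictions[i] == i)
    return float(ER_ITEM_POINTS * correct)


def score_internal_rotation(predicted_class: int) -> float:
    """CMS internal-rotation ladder: class c (1..6) -> 2*(c-1) points."""
    if predicted_class not in range(1, 7):
        raise ValueError(f"internal-rotation class {predicted_class} outside 1..6")
    return float(2 * (predicted_class - 1))


def score_elevation(angle: float) -> float:
    """CMS elevation ladder over 30-degree bands, upper-closed.

    [0,30] -> 0, (30,60] -> 2, (60,90] -> 4, (90,120] -> 6,
    (120,150] -> 8, (150,180] -> 10.
    """
    if not (0.0 <= angle <= 180.0):
        raise ValueError(f"elevation angle {angle} outside [0, 180]")
    if angle <= 30:
        return 0.0
    # ceil of (angle-30)/30, capped at 5 bands above the floor
    band = int(-(-(angle - 30.0) // 30.0))
    return float(2 * min(band, 5))


def class_from_dynamometer(force_lb: float) -> int:
    """Strength class 0-4 from dynamometer pounds.

    Left-closed bins [0,5), [5,10), [10,15), [15,20), [20, inf).
    """
    if force_lb < 0:
        raise ValueError("force must be non-negative")
    for cls, edge in enumerate(STRENGTH_BIN_EDGES):
        if force_lb < edge:
            return cls
    return 4


def strength_vote(
    segment_predictions: Sequence[Sequence[int]],
    unable_flag: bool = False,
) -> int:
    """Combine per-segment strength predictions into a final class.

    ``segment_predictions`` is one list of class predictions per repetition.
    Each repetition is reduced by majority vote (ties resolve to the lower
    class); the final class is the maximum across repetitions.  A subject
    unable to reach 90 degrees of abduction is class 0 unconditionally.
    """
    if unable_flag:
        return 0
    rep_votes = []
    for rep in segment_predictions:
        if len(rep) == 0:
            continue
        counts = Counter(int(c) for c in rep)
        top = max(counts.values())
        rep_votes.append(min(c for c, k in counts.items() if k == top))
    if not rep_votes:
        raise ValueError("no segment predictions and unable_flag not set")
    return max(rep_votes)


def strength_points(
    c: int, unable_flag: bool = False, mapping: str = "midpoint", pounds: float | None = None
) -> float:
    """CMS strength points (0-25) for a strength class.

    Default mapping uses pound-bin midpoints capped at 25 (CMS awards about
    one point per pound).  ``mapping='pounds'`` scores raw dynamometer
    pounds directly, capped at 25.  Unable subjects score 0.
    """
    if unable_flag:
        return 0.0
    if mapping == "pounds":
        if pounds is None:
            raise ValueError("mapping='pounds' requires the raw pounds value")
        return float(min(pounds, 25.0))
    if c not in range(5):
        raise ValueError(f"strength class {c} outside 0..4")
    try:
        return STRENGTH_POINT_MAPS[mapping][c]
    except KeyError:
        raise ValueError(f"unknown strength mapping {mapping!r}") from None


def score_subjective(pain_points: float, adl_points: float) -> tuple[float, float]:
    """Validated pass-through of questionnaire scores (pain 0-15, ADL 0-20)."""
    if not (0 <= pain_points <= 15):
        raise ValueError(f"pain {pain_points} outside [0, 15]")
    if not (0 <= adl_points <= 20):
        raise ValueError(f"ADL {adl_points} outside [0, 20]")
    return float(pain_points), float(adl_points)


def assemble_cms(
    pain: float, adl: float, er: float, ir: float, le: float, fe: float, strength: float
) -> CmsScore:
    """Assemble and range-check the full CMS score; total is the exact sum."""
    return CmsScore(pain=pain, adl=adl, er=er, ir=ir, le=le, fe=fe, strength=strength)
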