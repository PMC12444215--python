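"""Pose-landmark domain types, I/O and eligibility checks.

The scoring pipeline consumes per-image landmark sets produced upstream by
any human-pose-estimation backend.  Nine upper-body landmarks are used:
nose, both shoulders, both elbows, both wrists and both hips.  Coordinates
are normalized image coordinates (origin top-left, x right, y down);
an optional z channel carries relative depth.  Every landmark carries a
visibility score in [0, 1].
"""

from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

LANDMARK_NAMES: tuple[str, ...] = (
    "nose",
    "shoulder_L",
    "shoulder_R",
    "elbow_L",
    "elbow_R",
    "wrist_L",
    "wrist_R",
    "hip_L",
    "hip_R",
)

#: fixed landmark index table; the angle-feature ordering depends on it,
#: so it must never be reordered once models are trained.
LANDMARK_INDEX: dict[str, int] = {n: i for i, n in enumerate(LANDMARK_NAMES)}


class SchemaError(ValueError):
    """A record does not conform to the landmark file schema."""


class ModeError(ValueError):
    """3D operation requested on a 2D landmark set (or vice versa)."""


class MovementTask(str, enum.Enum):
    """The CMS movement tasks captured as single images."""

    external_rotation_item1 = "external_rotation_item1"
    external_rotation_item2 = "external_rotation_item2"
    external_rotation_item3 = "external_rotation_item3"
    external_rotation_item4 = "external_rotation_item4"
    internal_rotation = "internal_rotation"
    lateral_elevation = "lateral_elevation"
    forward_elevation = "forward_elevation"

    @property
    def item_number(self) -> int | None:
        """External-rotation item number (1-4), None for other tasks."""
        if self.value.startswith("external_rotation_item"):
            return int(self.value[-1])
        return None

    @property
    def is_external_rotation(self) -> bool:
        return self.item_number is not None


#: legal annotation classes per task: external rotation 1-4 plus 5 = unable;
#: internal rotation 1-6 (anatomical hand-reach levels); elevations 1-6
#: (30-degree angle bands).
TASK_CLASSES: dict[str, range] = {
    "external_rotation": range(1, 6),
    "internal_rotation": range(1, 7),
    "lateral_elevation": range(1, 7),
    "forward_elevation": range(1, 7),
}


def task_class_range(task: MovementTask) -> range:
    if task.is_external_rotation:
        return TASK_CLASSES["external_rotation"]
    return TASK_CLASSES[task.value]


@dataclass(frozen=True)
class Landmark:
    x: float
    y: float
    z: float | None
    visibility: float

    def __post_init__(self) -> None:
        coords = (self.x, self.y) + (() if self.z is None else (self.z,))
        if not all(math.isfinite(c) for c in coords):
            raise ValueError(f"non-finite landmark coordinate: {coords}")
        if not (0.0 <= self.visibility <= 1.0):
            raise ValueError(f"visibility {self.visibility} outside [0, 1]")


@dataclass
class LandmarkSet:
    """One image's 9 named landmarks plus task metadata.

    Invariants: exactly the 9 canonical landmark names; z present for all
    landmarks or for none (the coordinate mode is uniform per set).
    """

    landmarks: dict[str, Landmark]
    task: MovementTask
    side: str = "right"  # affected side: "left" | "right"

    def __post_init__(self) -> None:
        missing = set(LANDMARK_NAMES) - set(self.landmarks)
        extra = set(self.landmarks) - set(LANDMARK_NAMES)
        if missing or extra:
            raise SchemaError(
                f"landmark set must name exactly the 9 canonical landmarks; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        zs = [lm.z is not None for lm in self.landmarks.values()]
        if any(zs) and not all(zs):
            raise SchemaError("mixed 2D/3D landmarks within one set")

    @property
    def mode(self) -> str:
        """Coordinate mode of this set: '2D' or '3D'."""
        return "3D" if next(iter(self.landmarks.values())).z is not None else "2D"

    def coords(self, name: str, mode: str) -> tuple[float, ...]:
        lm = self.landmarks[name]
        if mode == "2D":
            return (lm.x, lm.y)
        if mode == "3D":
            if lm.z is None:
                raise ModeError("3D coordinates requested on a 2D landmark set")
            return (lm.x, lm.y, lm.z)
        raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class RomAnnotation:
    """Gold-standard class label for one range-of-motion image."""

    task: MovementTask
    class_label: int

    def __post_init__(self) -> None:
        legal = task_class_range(self.task)
        if self.class_label not in legal:
            raise ValueError(
                f"class {self.class_label} illegal for {self.task.value} "
                f"(legal: {legal.start}..{legal.stop - 1})"
            )


# ---------------------------------------------------------------------------
# I/O — JSON: one object per image; CSV: one row per image.

def _set_to_record(s: LandmarkSet) -> dict:
    rec: dict = {"task": s.task.value, "side": s.side, "mode": s.mode, "landmarks": {}}
    for name in LANDMARK_NAMES:
        lm = s.landmarks[name]
        vals = [lm.x, lm.y] + ([lm.z] if lm.z is not None else []) + [lm.visibility]
        rec["landmarks"][name] = vals
    return rec


def _record_to_set(rec: Mapping, where: str) -> LandmarkSet:
    try:
        task = MovementTask(rec["task"])
        side = rec.get("side", "right")
        raw = rec["landmarks"]
    except (KeyError, ValueError) as exc:
        raise SchemaError(f"{where}: malformed record ({exc})") from exc
    lms: dict[str, Landmark] = {}
    for name in LANDMARK_NAMES:
        if name not in raw:
            raise SchemaError(f"{where}: missing landmark {name!r}")
        vals = raw[name]
        if len(vals) == 3:
            x, y, v = vals
            z = None
        elif len(vals) == 4:
            x, y, z, v = vals
        else:
            raise SchemaError(f"{where}: landmark {name!r} has {len(vals)} values")
        lms[name] = Landmark(float(x), float(y), None if z is None else float(z), float(v))
    return LandmarkSet(lms, task, side)


def write_landmarks(sets: Iterable[LandmarkSet], path: str | Path, format: str = "json") -> None:
    """Write landmark sets to JSON (list of records) or CSV (one row each)."""
    path = Path(path)
    sets = list(sets)
    if format == "json":
        path.write_text(json.dumps([_set_to_record(s) for s in sets], indent=1))
    elif format == "csv":
        cols = ["task", "side"]
        for n in LANDMARK_NAMES:
            cols += [f"{n}_x", f"{n}_y", f"{n}_z", f"{n}_v"]
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for s in sets:
                row: list = [s.task.value, s.side]
                for n in LANDMARK_NAMES:
                    lm = s.landmarks[n]
                    row += [lm.x, lm.y, "" if lm.z is None else lm.z, lm.visibility]
                w.writerow(row)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_landmarks(path: str | Path, format: str | None = None) -> list[LandmarkSet]:
    """Read validated landmark sets from a JSON or CSV file, in file order.

    Mixed 2D/3D files are allowed; each set records its own coordinate mode.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "json"
    out: list[LandmarkSet] = []
    if format == "json":
        data = json.loads(path.read_text())
        if isinstance(data, Mapping):
            data = [data]
        for i, rec in enumerate(data):
            out.append(_record_to_set(rec, f"{path.name} record {i}"))
    elif format == "csv":
        with path.open(newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh)):
                raw: dict[str, list] = {}
                for n in LANDMARK_NAMES:
                    try:
                        x, y, zs, v = (row[f"{n}_{c}"] for c in "xyzv")
                    except KeyError as exc:
                        raise SchemaError(f"{path.name} row {i}: missing column {exc}") from exc
                    z = None if zs in ("", None) else float(zs)
                    raw[n] = [float(x), float(y)] + ([] if z is None else [z]) + [float(v)]
                out.append(
                    _record_to_set(
                        {"task": row["task"], "side": row.get("side", "right"), "landmarks": raw},
                        f"{path.name} row {i}",
                    )
                )
    else:
        raise ValueError(f"unknown format {format!r}")
    return out


# ---------------------------------------------------------------------------
# Eligibility — images must show the head and both hips.

#: default minimum visibility, matching the upstream detector's
#: minimum detection confidence of 0.5.
DEFAULT_MIN_VISIBILITY = 0.5

_REQUIRED_VISIBLE = ("nose", "hip_L", "hip_R")


def check_eligibility(
    s: LandmarkSet, min_visibility: float = DEFAULT_MIN_VISIBILITY
) -> tuple[bool, str]:
    """Image eligibility: the head (nose) and both hips must be visible.

    Returns (eligible, reason); the reason names every failing landmark.
    """
    failing = [n for n in _REQUIRED_VISIBLE if s.landmarks[n].visibility < min_visibility]
    if failing:
        return False, "low visibility: " + ", ".join(failing)
    return True, "ok"
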