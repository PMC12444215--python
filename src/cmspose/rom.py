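"""Angle-between-vectors features and direct elevation angles.

Each range-of-motion image is reduced to a purely geometric representation:
every directed vector between ordered pairs of the 9 landmarks is formed
(9 x 8 = 72 vectors), and the angle between every unordered pair of distinct
directed vectors is computed,

    theta = arccos( a . b / (|a| |b|) )     in degrees, [0, 180]

giving C(72, 2) = 2556 features per coordinate mode and 5112 when 2D and 3D
blocks are concatenated.  The enumeration order is fixed lexicographic over
the published landmark index table so trained models are portable.

Elevation tasks are scored directly: the angle between the upper-arm vector
(shoulder -> elbow) and the trunk-down vector (shoulder -> hip) on the
affected side.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .landmarks import LANDMARK_NAMES, LandmarkSet, ModeError, MovementTask

N_FEATURES_PER_MODE = 2556  # C(72, 2)
N_FEATURES_BOTH = 5112


class DegenerateVectorError(ValueError):
    """A zero-length (coincident-landmark) vector where one is required."""


class FeatureQualityError(ValueError):
    """Too many features are missing due to coincident landmarks."""


@dataclass
class AngleFeatureVector:
    """Ordered angle features for one image.

    ``values`` holds degrees in [0, 180]; coincident-landmark collisions
    yield NaN sentinels (imputed downstream).  ``mode`` is '2D', '3D' or
    'both' (2D block then 3D block).
    """

    values: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        expected = N_FEATURES_BOTH if self.mode == "both" else N_FEATURES_PER_MODE
        if self.values.shape != (expected,):
            raise ValueError(f"expected {expected} features, got {self.values.shape}")


def vector_between(s: LandmarkSet, from_name: str, to_name: str, mode: str = "2D") -> np.ndarray:
    """Componentwise (to - from) in the requested dimensionality."""
    if from_name == to_name:
        raise DegenerateVectorError(f"from == to == {from_name!r}")
    return np.asarray(s.coords(to_name, mode)) - np.asarray(s.coords(from_name, mode))


def angle_between(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees between two vectors, clamped into [0, 180]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateVectorError("zero-length vector has no direction")
    cos = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


@lru_cache(maxsize=None)
def directed_pairs() -> tuple[tuple[int, int], ...]:
    """The 72 ordered landmark-index pairs, lexicographic."""
    n = len(LANDMARK_NAMES)
    return tuple((i, j) for i in range(n) for j in range(n) if i != j)


@lru_cache(maxsize=None)
def feature_index(mode: str = "2D") -> tuple[tuple[tuple[int, int], tuple[int, int], str], ...]:
    """Total, injective map feature position -> (vector1, vector2, mode).

    Vectors are ordered landmark-index pairs; feature order is lexicographic
    over (vector1 position, vector2 position) within each mode block.
    """
    pairs = directed_pairs()
    if mode == "both":
        return feature_index("2D") + feature_index("3D")
    return tuple(
        (pairs[p], pairs[q], mode)
        for p in range(len(pairs))
        for q in range(p + 1, len(pairs))
    )


def feature_names(mode: str = "2D") -> list[str]:
    """Human-readable column names, e.g. 'ang2D[nose>hip_L|wrist_R>elbow_R]'."""
    out = []
    for (f1, t1), (f2, t2), m in feature_index(mode):
        out.append(
            f"ang{m}[{LANDMARK_NAMES[f1]}>{LANDMARK_NAMES[t1]}|"
            f"{LANDMARK_NAMES[f2]}>{LANDMARK_NAMES[t2]}]"
        )
    return out


def _mode_block(s: LandmarkSet, mode: str) -> np.ndarray:
    pts = np.array([s.coords(n, mode) for n in LANDMARK_NAMES], dtype=float)
    pairs = np.array(directed_pairs())
    vecs = pts[pairs[:, 1]] - pts[pairs[:, 0]]  # (72, d)
    norms = np.linalg.norm(vecs, axis=1)
    # coincident landmarks -> zero vectors -> NaN sentinel, not an abort
    safe = np.where(norms == 0.0, 1.0, norms)
    unit = vecs / safe[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    ang = np.degrees(np.arccos(cos))
    bad = norms == 0.0
    ang[bad, :] = np.nan
    ang[:, bad] = np.nan
    iu = np.triu_indices(len(pairs), k=1)
    return ang[iu]


def generate_angle_features(s: LandmarkSet, mode: str = "2D") -> AngleFeatureVector:
    """All pairwise vector angles for one landmark set.

    2556 features for mode '2D' or '3D'; 5112 for 'both' (2D block first).
    Raises FeatureQualityError when more than half the features are missing
    (severe landmark collisions), naming the colliding landmarks.
    """
    if mode in ("3D", "both") and s.mode != "3D":
        raise ModeError(f"mode {mode!r} requested on a {s.mode} landmark set")
    if mode == "both":
        vals = np.concatenate([_mode_block(s, "2D"), _mode_block(s, "3D")])
    elif mode in ("2D", "3D"):
        vals = _mode_block(s, mode)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n_missing = int(np.isnan(vals).sum())
    if n_missing > 0.5 * vals.size:
        collisions = _collisions(s)
        raise FeatureQualityError(
            f"{n_missing}/{vals.size} features missing; coincident landmarks: {collisions}"
        )
    return AngleFeatureVector(vals, mode)


def _collisions(s: LandmarkSet) -> list[tuple[str, str]]:
    out = []
    for i, a in enumerate(LANDMARK_NAMES):
        for b in LANDMARK_NAMES[i + 1 :]:
            if s.coords(a, s.mode) == s.coords(b, s.mode):
                out.append((a, b))
    return out


def feature_matrix(sets: list[LandmarkSet], mode: str = "2D") -> np.ndarray:
    """Stack angle features for many images into an (n, p) matrix."""
    return np.vstack([generate_angle_features(s, mode).values for s in sets])


_ELEVATION_TASKS = (MovementTask.lateral_elevation, MovementTask.forward_elevation)


def elevation_angle(s: LandmarkSet) -> float:
    """Arm-elevation angle on the affected side, degrees in [0, 180].

    Angle between the upper-arm vector (shoulder -> elbow) and the
    trunk-down vector (shoulder -> hip).  0 means the arm hangs along the
    trunk; 180 means fully raised.
    """
    if s.task not in _ELEVATION_TASKS:
        raise ValueError(f"elevation angle undefined for task {s.task.value}")
    suffix = "L" if s.side == "left" else "R"
    arm = vector_between(s, f"shoulder_{suffix}", f"elbow_{suffix}", s.mode)
    trunk = vector_between(s, f"shoulder_{suffix}", f"hip_{suffix}", s.mode)
    return angle_between(arm, trunk)
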