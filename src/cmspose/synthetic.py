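"""Synthetic cohorts: class-conditional postures and abduction signals.

The generator makes every pipeline stage testable without patient data.

Postures come from a stick-figure forward model: a fixed trunk (nose,
shoulders, hips) in normalized image coordinates (origin top-left, y down,
z toward the camera) with the affected arm posed per task and class:

* external rotation — four functional postures (hand behind / on top of the
  head with the elbow forward or back) as classes 1-4, plus class 5 = the
  arm hanging at the side (unable to perform);
* internal rotation — the hand reaching behind the back to six anatomical
  levels (lateral thigh, buttock, sacrum, waist, T12, interscapular);
* elevations — the arm raised at the class band's midpoint angle from the
  trunk line (class c -> 30(c-1)+15 degrees).

Strength sessions are a deterministic oscillation model: tri-axial
acceleration with gravity offset plus a sinusoid whose amplitude increases
strictly and whose frequency increases with strength class, plus white
Gaussian sensor noise.  The model is not a biomechanical simulation; its
job is to carry class-separable time/frequency signatures.

All randomness flows from one cohort seed via numpy SeedSequence spawning,
so cohorts are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imu import DEFAULT_DURATION, DEFAULT_FS, ImuSession, write_imu_csv
from .landmarks import (
    LANDMARK_NAMES,
    Landmark,
    LandmarkSet,
    MovementTask,
    task_class_range,
    write_landmarks,
)

#: default landmark jitter, normalized image units (a few percent of the
#: image, typical pose-estimator noise)
DEFAULT_POSE_NOISE_SD = 0.02
#: default accelerometer noise SD, m/s^2
DEFAULT_IMU_NOISE_SD = 0.5

GRAVITY = 9.81

# ---------------------------------------------------------------------------
# trunk template (3D, normalized image coordinates, affected side = right)

_TRUNK = {
    "nose": (0.50, 0.15, 0.05),
    "shoulder_L": (0.38, 0.35, 0.0),
    "shoulder_R": (0.62, 0.35, 0.0),
    "hip_L": (0.42, 0.80, 0.0),
    "hip_R": (0.58, 0.80, 0.0),
}
_UPPER_ARM = 0.20
_FOREARM = 0.18

#: external-rotation arm poses, class -> (elbow, wrist); classes 1-4 are the
#: four photographed items, class 5 is the failure posture (arm at side)
_ER_ARM = {
    1: ((0.66, 0.28, 0.08), (0.55, 0.17, -0.05)),  # hand behind head, elbow forward
    2: ((0.76, 0.22, -0.10), (0.55, 0.17, -0.05)),  # hand behind head, elbow back
    3: ((0.64, 0.16, 0.08), (0.50, 0.05, 0.00)),  # hand on top of head, elbow forward
    4: ((0.74, 0.12, -0.10), (0.50, 0.05, 0.00)),  # hand on top of head, elbow back
    5: ((0.64, 0.55, 0.0), (0.65, 0.73, 0.0)),  # unable: arm hangs at the side
}

#: internal-rotation hand-reach levels, class -> (elbow, wrist)
_IR_ARM = {
    1: ((0.72, 0.62, -0.02), (0.66, 0.85, -0.06)),  # lateral thigh
    2: ((0.74, 0.58, -0.03), (0.58, 0.78, -0.06)),  # buttock
    3: ((0.75, 0.55, -0.04), (0.50, 0.72, -0.07)),  # sacrum / lumbosacral
    4: ((0.76, 0.50, -0.04), (0.50, 0.62, -0.07)),  # waist (L3)
    5: ((0.77, 0.44, -0.05), (0.50, 0.52, -0.08)),  # T12
    6: ((0.78, 0.38, -0.05), (0.50, 0.42, -0.08)),  # interscapular (T7)
}


def elevation_band_midpoint(class_label: int) -> float:
    """Target elevation angle (degrees) for a class band: 30(c-1)+15."""
    return 30.0 * (class_label - 1) + 15.0


def _elevation_arm(task: MovementTask, angle_deg: float) -> tuple[tuple, tuple]:
    """Elbow/wrist for the right arm elevated ``angle_deg`` from the trunk line."""
    sh = np.array(_TRUNK["shoulder_R"])
    hip = np.array(_TRUNK["hip_R"])
    u = hip - sh
    u /= np.linalg.norm(u)
    th = np.radians(angle_deg)
    if task is MovementTask.lateral_elevation:
        # rotate the trunk-down direction outward in the image plane (+x)
        perp = np.array([-u[1], u[0], 0.0])
    else:
        # forward elevation: rotate toward the camera (+z)
        perp = np.array([0.0, 0.0, 1.0])
    d = np.cos(th) * u + np.sin(th) * perp
    elbow = sh + _UPPER_ARM * d
    wrist = sh + (_UPPER_ARM + _FOREARM) * d
    return tuple(elbow), tuple(wrist)


@dataclass(frozen=True)
class PostureTemplate:
    """Canonical noiseless 3D coordinates for one (task, class)."""

    task: MovementTask
    class_label: int
    coords: dict[str, tuple[float, float, float]]


def posture_template(task: MovementTask, class_label: int) -> PostureTemplate:
    if class_label not in task_class_range(task):
        raise ValueError(f"class {class_label} illegal for {task.value}")
    coords = dict(_TRUNK)
    if task.is_external_rotation or task is MovementTask.internal_rotation:
        arm = _ER_ARM if task.is_external_rotation else _IR_ARM
        elbow, wrist = arm[class_label]
    else:
        elbow, wrist = _elevation_arm(task, elevation_band_midpoint(class_label))
    coords["elbow_R"] = tuple(elbow)
    coords["wrist_R"] = tuple(wrist)
    # unaffected arm hangs straight down
    shl = np.array(coords["shoulder_L"])
    coords["elbow_L"] = tuple(shl + np.array([0.0, _UPPER_ARM, 0.0]))
    coords["wrist_L"] = tuple(shl + np.array([0.0, _UPPER_ARM + _FOREARM, 0.0]))
    return PostureTemplate(task, class_label, coords)


def generate_posture(
    task: MovementTask,
    class_label: int,
    noise_sd: float = DEFAULT_POSE_NOISE_SD,
    seed: int | np.random.Generator = 0,
) -> LandmarkSet:
    """A 3D landmark set: the (task, class) template plus isotropic
    Gaussian landmark noise.  All visibilities are 1.0, so every generated
    posture passes eligibility.
    """
    tpl = posture_template(task, class_label)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lms = {}
    for name in LANDMARK_NAMES:
        xyz = np.array(tpl.coords[name]) + rng.normal(0.0, noise_sd, size=3)
        lms[name] = Landmark(float(xyz[0]), float(xyz[1]), float(xyz[2]), 1.0)
    return LandmarkSet(lms, task, side="right")


# ---------------------------------------------------------------------------
# strength signal model

#: strength class -> oscillation amplitude (m/s^2); strictly increasing
CLASS_AMPLITUDE = (0.8, 1.6, 2.6, 3.8, 5.2)
#: strength class -> oscillation frequency (Hz); nondecreasing, on 0.5 Hz
#: bins so a 2 s window holds an integer number of cycles
CLASS_FREQUENCY = (0.5, 1.0, 1.5, 2.0, 2.5)


def generate_imu_session(
    strength_class: int,
    fs: float = DEFAULT_FS,
    duration: float = DEFAULT_DURATION,
    noise_sd: float = DEFAULT_IMU_NOISE_SD,
    seed: int | np.random.Generator = 0,
    unable_flag: bool = False,
    repetition_index: int = 1,
) -> ImuSession:
    """One synthetic abduction recording for a strength class 0-4.

    The arm oscillates at the class frequency with the class amplitude;
    gravity sits mostly on the z axis; white Gaussian noise is added on all
    axes.  Sample count = round(fs * duration).
    """
    if strength_class not in range(5):
        raise ValueError(f"strength class {strength_class} outside 0..4")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    a = CLASS_AMPLITUDE[strength_class]
    f = CLASS_FREQUENCY[strength_class]
    w = 2.0 * np.pi * f
    ax = 0.6 * a * np.sin(w * t + np.pi / 4)
    ay = 0.3 * a * np.sin(w * t + np.pi / 2)
    az = GRAVITY + a * np.sin(w * t)
    samples = np.column_stack([ax, ay, az]) + rng.normal(0.0, noise_sd, size=(n, 3))
    return ImuSession(
        samples,
        sampling_rate=fs,
        repetition_index=repetition_index,
        unable_flag=unable_flag,
    )


# ---------------------------------------------------------------------------
# cohorts

#: fixed sub-stream ids for SeedSequence splitting (one per task group)
_GROUP_STREAM = {
    "external_rotation": 1,
    "internal_rotation": 2,
    "lateral_elevation": 3,
    "forward_elevation": 4,
}


@dataclass
class RomCohort:
    """Labelled posture sets for one task group, split train/test."""

    task: MovementTask | None  # None for pooled external-rotation items
    train_sets: list[LandmarkSet]
    train_labels: np.ndarray
    train_subjects: list[str]
    test_sets: list[LandmarkSet]
    test_labels: np.ndarray
    test_subjects: list[str]


@dataclass
class StrengthCohort:
    """Per-subject repetition pairs of abduction sessions, split train/test."""

    train_sessions: list[list[ImuSession]]
    train_labels: np.ndarray
    train_subjects: list[str]
    test_sessions: list[list[ImuSession]]
    test_labels: np.ndarray
    test_subjects: list[str]


def _rom_task_cohort(
    tasks_for_class: dict[int, MovementTask],
    n_per_class: int,
    n_test_per_class: int,
    noise_sd: float,
    rng: np.random.Generator,
    prefix: str,
) -> RomCohort:
    tr_sets, tr_y, tr_id = [], [], []
    te_sets, te_y, te_id = [], [], []
    for cls, task in tasks_for_class.items():
        for i in range(n_per_class):
            tr_sets.append(generate_posture(task, cls, noise_sd, rng))
            tr_y.append(cls)
            tr_id.append(f"{prefix}_c{cls}_train{i}")
        for i in range(n_test_per_class):
            te_sets.append(generate_posture(task, cls, noise_sd, rng))
            te_y.append(cls)
            te_id.append(f"{prefix}_c{cls}_test{i}")
    task = next(iter(tasks_for_class.values()))
    pooled = len(set(tasks_for_class.values())) > 1
    return RomCohort(
        None if pooled else task,
        tr_sets, np.array(tr_y), tr_id,
        te_sets, np.array(te_y), te_id,
    )


def generate_rom_cohort(
    task_group: str,
    n_per_class: int = 10,
    n_test_per_class: int = 4,
    noise_sd: float = DEFAULT_POSE_NOISE_SD,
    seed: int = 0,
) -> RomCohort:
    """Posture cohort for 'external_rotation', 'internal_rotation',
    'lateral_elevation' or 'forward_elevation'.

    External rotation pools images of the four items plus failures: class
    1-4 images carry the corresponding item task, class-5 images are failed
    attempts (attributed to item 1; the failure posture is task-agnostic).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, _GROUP_STREAM[task_group]]))
    if task_group == "external_rotation":
        tasks = {c: MovementTask(f"external_rotation_item{c}") for c in range(1, 5)}
        tasks[5] = MovementTask.external_rotation_item1
    elif task_group in ("internal_rotation", "lateral_elevation", "forward_elevation"):
        task = MovementTask(task_group)
        tasks = {c: task for c in task_class_range(task)}
    else:
        raise ValueError(f"unknown task group {task_group!r}")
    return _rom_task_cohort(tasks, n_per_class, n_test_per_class, noise_sd, rng, task_group[:2])


def generate_strength_cohort(
    n_per_class: int = 10,
    n_test_per_class: int = 4,
    noise_sd: float = DEFAULT_IMU_NOISE_SD,
    seed: int = 0,
    repetitions: int = 2,
) -> StrengthCohort:
    """Abduction-session cohort over strength classes 0-4, two repetitions
    per subject, disjoint train/test subjects."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 915]))
    tr_s, tr_y, tr_id = [], [], []
    te_s, te_y, te_id = [], [], []
    for cls in range(5):
        for split, n, sess_list, y, ids in (
            ("train", n_per_class, tr_s, tr_y, tr_id),
            ("test", n_test_per_class, te_s, te_y, te_id),
        ):
            for i in range(n):
                reps = [
                    generate_imu_session(cls, noise_sd=noise_sd, seed=rng, repetition_index=r + 1)
                    for r in range(repetitions)
                ]
                sess_list.append(reps)
                y.append(cls)
                ids.append(f"st_c{cls}_{split}{i}")
    return StrengthCohort(tr_s, np.array(tr_y), tr_id, te_s, np.array(te_y), te_id)


def generate_reference_postures(
    task_group: str,
    kind: str,
    n: int = 5,
    noise_sd: float = DEFAULT_POSE_NOISE_SD,
    seed: int = 0,
) -> tuple[list[LandmarkSet], np.ndarray]:
    """Reference exemplars: 'positive' = healthy volunteers performing the
    top class correctly; 'negative' = severely impaired function (the lowest
    / failure class)."""
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, 77, {"positive": 1, "negative": 2}[kind]])
    )
    if task_group == "external_rotation":
        cls = {"positive": 4, "negative": 5}[kind]
        task = MovementTask.external_rotation_item4 if kind == "positive" else MovementTask.external_rotation_item1
    else:
        task = MovementTask(task_group)
        legal = task_class_range(task)
        cls = {"positive": legal.stop - 1, "negative": legal.start}[kind]
    sets = [generate_posture(task, cls, noise_sd, rng) for _ in range(n)]
    return sets, np.full(n, cls)


def write_cohort_files(
    rom_cohorts: dict[str, RomCohort],
    strength: StrengthCohort | None,
    out_dir: str | Path,
) -> Path:
    """Emit landmark JSON and sensor CSV files plus a manifest listing every
    generated file with its label and split."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    for group, cohort in rom_cohorts.items():
        for split, sets, labels, ids in (
            ("train", cohort.train_sets, cohort.train_labels, cohort.train_subjects),
            ("test", cohort.test_sets, cohort.test_labels, cohort.test_subjects),
        ):
            path = out_dir / f"{group}_{split}.json"
            write_landmarks(sets, path, "json")
            manifest.append(
                {
                    "file": path.name,
                    "kind": "landmarks",
                    "task_group": group,
                    "split": split,
                    "labels": np.asarray(labels).tolist(),
                    "subjects": list(ids),
                }
            )
    if strength is not None:
        imu_dir = out_dir / "imu"
        imu_dir.mkdir(exist_ok=True)
        for split, sessions, labels, ids in (
            ("train", strength.train_sessions, strength.train_labels, strength.train_subjects),
            ("test", strength.test_sessions, strength.test_labels, strength.test_subjects),
        ):
            for subj, label, reps in zip(ids, labels, sessions):
                for rep in reps:
                    path = imu_dir / f"{subj}_rep{rep.repetition_index}.csv"
                    write_imu_csv(rep, path)
                    manifest.append(
                        {
                            "file": f"imu/{path.name}",
                            "kind": "imu",
                            "split": split,
                            "label": int(label),
                            "subject": subj,
                            "repetition": rep.repetition_index,
                        }
                    )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir
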