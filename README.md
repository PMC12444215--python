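# cmspose

Automated **Constant–Murley Scale (CMS)** shoulder-function scoring from
pose landmarks and phone inertial sensors, plus the inter-rater agreement
framework (Cohen κ, ICC, mean differences) used to validate automated
scores against human raters.

The CMS awards 100 points: pain (15) + activities of daily living (20) +
range of motion (40: forward elevation, lateral elevation, external
rotation, internal rotation, 10 points each) + abduction strength (25).
`cmspose` computes the objective components remotely:

- **Range of motion** — single images of functional postures are reduced
  upstream (e.g. by BlazePose) to 9 landmarks (nose, shoulders, elbows,
  wrists, hips). Every pair of directed inter-landmark vectors yields an
  angle θ = arccos(a·b/|a||b|): 2556 features per coordinate mode, 5112
  across 2D+3D. External/internal rotation postures are classified
  (six model families with PCA + grid search + stratified 5-fold CV);
  elevations are measured directly as the shoulder→elbow vs shoulder→hip
  angle and banded on the CMS 30° ladder.
- **Strength** — 10 s, 50 Hz tri-axial abduction recordings are low-pass
  filtered (Butterworth, 10 Hz, order 8, zero-phase), segmented into eight
  2 s windows (1 s step), featurized (60 time/frequency statistics per
  segment) and classified into dynamometer pound-bin classes 0–4; segment
  votes combine by per-repetition majority (ties to the lower class) and
  the maximum across repetitions; subjects unable to reach 90° abduction
  score 0.
- **Validation** — unweighted Cohen κ with Landis–Koch bands, one-way
  random-effects single-rater ICC(1,1), mean (SD) differences and confusion
  matrices, as an agreement report per score variable.

A seeded synthetic-cohort generator (stick-figure postures, oscillation
strength signals) makes the full pipeline testable end to end without
patient data. See `docs/methods.md` for the model details and conventions.

## Worked example

```python
import numpy as np
from cmspose import RunConfig, assess_subject
from cmspose.pipeline import rom_training_dataset, strength_training_dataset, train_task_models
from cmspose.synthetic import (
    generate_imu_session, generate_posture, generate_rom_cohort,
    generate_strength_cohort,
)
from cmspose.landmarks import MovementTask

cfg = RunConfig(seed=1, families=("knn",))

# train internal-rotation and strength classifiers on a synthetic cohort
ir = generate_rom_cohort("internal_rotation", n_per_class=8, seed=1)
ir_model = train_task_models(rom_training_dataset(ir.train_sets, ir.train_labels, "2D"), cfg)[0]["knn"]
st = generate_strength_cohort(n_per_class=8, seed=1)
st_model = train_task_models(strength_training_dataset(st.train_sessions, st.train_labels, cfg), cfg)[0]["knn"]

# assess one subject: IR level 4, lateral elevation in the (120,150] band,
# strength class 3, pain 10/15, ADL 15/20
report = assess_subject(
    er_model=None, ir_model=ir_model, strength_model=st_model,
    er_images=None,
    ir_image=generate_posture(MovementTask.internal_rotation, 4, 0.02, seed=7),
    le_image=generate_posture(MovementTask.lateral_elevation, 5, 0.02, seed=8),
    fe_image=None,
    strength_sessions=[generate_imu_session(3, seed=r, repetition_index=r) for r in (1, 2)],
    pain=10, adl=15, config=cfg,
)
print(report["components"])
print("missing:", report["missing"])
```

prints

```
{'pain': 10.0, 'adl': 15.0, 'er': 0.0, 'ir': 6.0, 'le': 8.0, 'fe': 0.0, 'strength': 17.5, 'total': 56.5}
missing: ['er', 'fe']
```

`ir: 6.0` is the CMS ladder value for reach level 4 (2×(4−1)); `le: 8.0` is
the (120,150]° elevation band; `strength: 17.5` is the midpoint-pounds value
for class 3; absent external-rotation images and forward-elevation image are
reported as missing components, not silently scored.

The same pipeline is scriptable from a shell:

```bash
cmspose generate cohort/ --seed 1
cmspose featurize cohort/internal_rotation_train.json features.csv --mode 2D
cmspose train cohort/ models/ --task-group internal_rotation --seed 1
cmspose assess models/ subject/ score.json --pain 10 --adl 15
cmspose validate predictions.csv gold.csv agreement.csv
```

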