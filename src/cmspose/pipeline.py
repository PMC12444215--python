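"""End-to-end orchestration: featurize -> train -> assess -> validate.

Bridges the geometry/signal modules and the classifier bank, and assembles
per-subject CMS reports.  The run configuration carries every pipeline
default (filter cutoff 10 Hz, order 8, window 2 s, step 1 s, 50 Hz sampling,
5 folds, detection confidence 0.5) and validates before any computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import imu as imu_mod
from . import rom as rom_mod
from .agreement import agreement_report
from .landmarks import DEFAULT_MIN_VISIBILITY, LandmarkSet, check_eligibility
from .scoring import (
    assemble_cms,
    score_elevation,
    score_external_rotation,
    score_internal_rotation,
    score_subjective,
    strength_points,
    strength_vote,
)
from .training import (
    DEFAULT_GRIDS,
    MODEL_FAMILIES,
    TrainedClassifier,
    TrainingDataset,
    augment_with_references,
    fit_pipeline,
    oversample_minority,
)


class RunConfig(BaseModel):
    """Validated run configuration; defaults are the pipeline's operating
    parameters (see docs/methods.md)."""

    mode: str = "2D"  # angle-feature coordinate mode: 2D | 3D | both
    use_positive_reference: bool = True
    use_negative_reference: bool = True
    oversample: bool = True
    filter_cutoff_hz: float = Field(default=10.0, gt=0)
    filter_order: int = Field(default=8, ge=1)
    window_s: float = Field(default=2.0, gt=0)
    step_s: float = Field(default=1.0, gt=0)
    sampling_rate_hz: float = Field(default=50.0, gt=0)
    folds: int = Field(default=5, ge=2)
    min_visibility: float = Field(default=DEFAULT_MIN_VISIBILITY, ge=0, le=1)
    variance_retained: float = Field(default=0.95, gt=0, lt=1)
    families: tuple[str, ...] = MODEL_FAMILIES
    strength_mapping: str = "midpoint"  # midpoint | class_step | pounds
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.mode not in ("2D", "3D", "both"):
            raise ValueError(f"mode must be 2D/3D/both, got {self.mode!r}")
        unknown = set(self.families) - set(MODEL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")
        if self.filter_cutoff_hz >= self.sampling_rate_hz / 2:
            raise ValueError("filter cutoff must be below Nyquist")
        return self


# ---------------------------------------------------------------------------
# featurization bridges

def rom_training_dataset(
    sets: list[LandmarkSet],
    labels: np.ndarray,
    mode: str = "2D",
    min_visibility: float = DEFAULT_MIN_VISIBILITY,
    provenance: str = "patient",
) -> TrainingDataset:
    """Angle-feature matrix for labelled posture images.

    Ineligible images (head or hip not visible) are excluded, mirroring the
    image-collection rule; their labels are dropped with them.
    """
    keep = [i for i, s in enumerate(sets) if check_eligibility(s, min_visibility)[0]]
    X = rom_mod.feature_matrix([sets[i] for i in keep], mode)
    df = pd.DataFrame(X, columns=rom_mod.feature_names(mode))
    return TrainingDataset(
        df, np.asarray(labels)[keep], np.full(len(keep), provenance, dtype=object)
    )


def strength_training_dataset(
    sessions: list[list[imu_mod.ImuSession]],
    labels: np.ndarray,
    config: RunConfig | None = None,
    provenance: str = "patient",
) -> TrainingDataset:
    """Segment-level feature matrix: every 2 s segment of every repetition
    becomes one training row carrying its session's strength class."""
    cfg = config or RunConfig()
    frames, ys = [], []
    for reps, label in zip(sessions, labels):
        for session in reps:
            f = imu_mod.session_feature_frame(
                session, cfg.filter_cutoff_hz, cfg.filter_order, cfg.window_s, cfg.step_s
            )
            frames.append(f)
            ys.append(np.full(len(f), label))
    X = pd.concat(frames, ignore_index=True)
    y = np.concatenate(ys)
    return TrainingDataset(X, y, np.full(len(y), provenance, dtype=object))


# ---------------------------------------------------------------------------
# training

def train_task_models(
    patient: TrainingDataset,
    config: RunConfig,
    positive: TrainingDataset | None = None,
    negative: TrainingDataset | None = None,
    oversample: bool | None = None,
    families: tuple[str, ...] | None = None,
) -> tuple[dict[str, TrainedClassifier], pd.DataFrame]:
    """Fit every requested model family on one task's data.

    Returns the fitted classifiers and a CV report (one row per family with
    mean and per-fold accuracies), shaped like the training-comparison
    tables (toggle settings x family columns).
    """
    data = augment_with_references(
        patient,
        positive,
        negative,
        use_positive=config.use_positive_reference,
        use_negative=config.use_negative_reference,
    )
    do_oversample = config.oversample if oversample is None else oversample
    if do_oversample and len(data.class_counts()) > 1:
        data = oversample_minority(data, config.seed)
    models: dict[str, TrainedClassifier] = {}
    rows = []
    for family in families or config.families:
        model = fit_pipeline(
            data,
            family,
            variance_retained=config.variance_retained,
            folds=config.folds,
            seed=config.seed,
        )
        models[family] = model
        rows.append(
            {
                "family": family,
                "cv_accuracy": model.cv_accuracy,
                **{f"fold{k}": a for k, a in enumerate(model.fold_accuracies)},
                "best_params": str(model.best_params),
            }
        )
    return models, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# assessment

def predict_strength_class(
    model: TrainedClassifier,
    sessions: list[imu_mod.ImuSession],
    config: RunConfig | None = None,
) -> int:
    """Session repetitions -> per-segment predictions -> voted class."""
    cfg = config or RunConfig()
    unable = any(s.unable_flag for s in sessions)
    per_rep = []
    for session in sessions:
        f = imu_mod.session_feature_frame(
            session, cfg.filter_cutoff_hz, cfg.filter_order, cfg.window_s, cfg.step_s
        )
        per_rep.append(model.predict(f).tolist() if len(f) else [])
    return strength_vote(per_rep, unable_flag=unable)


def assess_subject(
    er_model: TrainedClassifier | None,
    ir_model: TrainedClassifier | None,
    strength_model: TrainedClassifier | None,
    er_images: dict[int, LandmarkSet] | None,
    ir_image: LandmarkSet | None,
    le_image: LandmarkSet | None,
    fe_image: LandmarkSet | None,
    strength_sessions: list[imu_mod.ImuSession] | None,
    pain: float,
    adl: float,
    config: RunConfig | None = None,
) -> dict:
    """Full CMS assessment of one subject from raw inputs.

    Missing modalities yield an explicit ``missing`` list in the report (the
    affected components score 0); ineligible images are reported, never
    silently dropped.
    """
    cfg = config or RunConfig()
    pain, adl = score_subjective(pain, adl)
    missing: list[str] = []
    ineligible: list[str] = []
    provenance: dict = {}

    def eligible(img: LandmarkSet, name: str) -> bool:
        ok, reason = check_eligibility(img, cfg.min_visibility)
        if not ok:
            ineligible.append(f"{name}: {reason}")
        return ok

    er = ir = le = fe = st = 0.0
    if er_model is not None and er_images:
        preds = {}
        for item, img in sorted(er_images.items()):
            if eligible(img, f"er_item{item}"):
                feats = rom_mod.generate_angle_features(img, cfg.mode).values
                preds[item] = int(er_model.predict(feats[None, :])[0])
            else:
                preds[item] = 5  # unusable image cannot evidence a match
        er = score_external_rotation(preds)
        provenance["er_predictions"] = preds
    else:
        missing.append("er")
    if ir_model is not None and ir_image is not None and eligible(ir_image, "ir"):
        feats = rom_mod.generate_angle_features(ir_image, cfg.mode).values
        cls = int(ir_model.predict(feats[None, :])[0])
        ir = score_internal_rotation(cls)
        provenance["ir_prediction"] = cls
    else:
        missing.append("ir")
    for name, img in (("le", le_image), ("fe", fe_image)):
        if img is not None and eligible(img, name):
            angle = rom_mod.elevation_angle(img)
            pts = score_elevation(angle)
            provenance[f"{name}_angle_deg"] = angle
            if name == "le":
                le = pts
            else:
                fe = pts
        else:
            missing.append(name)
    if strength_model is not None and strength_sessions:
        cls = predict_strength_class(strength_model, strength_sessions, cfg)
        unable = any(s.unable_flag for s in strength_sessions)
        st = strength_points(cls, unable_flag=unable, mapping=cfg.strength_mapping)
        provenance["strength_class"] = cls
        provenance["unable_flag"] = unable
    else:
        missing.append("strength")
    score = assemble_cms(pain, adl, er, ir, le, fe, st)
    return {
        "components": score.as_dict(),
        "missing": missing,
        "ineligible": ineligible,
        "provenance": provenance,
    }


def validate_predictions(
    predictions: pd.DataFrame, gold: pd.DataFrame, variables: list[str] | None = None
) -> pd.DataFrame:
    """Agreement report between system outputs and gold-standard scores.

    Both frames are indexed by subject id; mismatched ids raise with the
    orphan list.
    """
    orphans = set(predictions.index) ^ set(gold.index)
    if orphans:
        raise ValueError(f"subject ids do not match; orphans: {sorted(orphans)}")
    gold = gold.loc[predictions.index]
    cols = variables or [c for c in predictions.columns if c in gold.columns]
    return agreement_report(
        {c: (predictions[c].to_numpy(), gold[c].to_numpy()) for c in cols}
    )
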