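"""Patient-specific evaluation harnesses.

Four designs mirror the cross-dataset and leave-one-subject-out protocols
(train on one dataset, test on the other; LOSOCV within a dataset), plus
beat-level hold-out and stratified k-fold baselines.  Cross-validation
aggregates fold confusion matrices by element-wise summation (micro), so
the aggregate matrix total always equals the dataset size; per-fold
matrices are also returned for macro-style reporting.

A ``trainer`` callable can be injected for testing; the default builds a
residual-network classifier and fine-tunes it under the training module's
protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .beats import RenderConfig, label_beats, render_beat_image, segment_beats
from .metrics import ConfusionMatrix, MetricsReport, confusion, metrics
from .nn import ResNetSpec, build_model, resnet_tiny_spec
from .pantompkins import detect_r_peaks
from .records import AnnotatedRecord, BeatLabel
from .training import BeatDataset, TrainConfig, fit

#: trainer(train_ds, cfg, eval_subjects) -> predict(images) -> 0/1 labels
Trainer = Callable[[BeatDataset, TrainConfig, set[str]], Callable[[np.ndarray], np.ndarray]]


def build_dataset(
    records: Sequence[AnnotatedRecord],
    render_cfg: RenderConfig | None = None,
    anchor: str = "annotation",
    tolerance_s: float = 0.15,
) -> BeatDataset:
    """Segment, label and render every record into a BeatDataset.

    ``anchor`` selects what positions the beat windows are built on:
    reference annotation indices ("annotation", the training convention)
    or Pan-Tompkins detections ("detector").
    """
    if anchor not in {"annotation", "detector"}:
        raise ValueError(f"anchor must be 'annotation' or 'detector', got {anchor!r}")
    render_cfg = render_cfg or RenderConfig()
    images, labels, subjects = [], [], []
    for rec in records:
        if anchor == "annotation":
            peaks = [a.sample_index for a in rec.annotations]
        else:
            peaks = detect_r_peaks(rec)
        beats = segment_beats(rec, peaks)
        beats = label_beats(beats, rec.annotations, rec.sampling_rate_hz, tolerance_s)
        for b in beats:
            images.append(render_beat_image(b, render_cfg).to_chw_float())
            labels.append(0 if b.label is BeatLabel.NORMAL else 1)
            subjects.append(rec.subject_id)
    if not images:
        return BeatDataset(
            np.zeros((0, 3, render_cfg.height, render_cfg.width), dtype=np.float32),
            np.zeros(0, dtype=np.int64),
            np.array([], dtype=object),
        )
    return BeatDataset(np.stack(images), np.array(labels), np.array(subjects))


def default_trainer(model_spec: ResNetSpec | None = None) -> Trainer:
    spec = model_spec or resnet_tiny_spec()

    def trainer(train_ds: BeatDataset, cfg: TrainConfig, eval_subjects: set[str]):
        model = build_model(spec, seed=cfg.seed)
        model, history = fit(model, train_ds, cfg, eval_subjects=eval_subjects)

        def predict(images: np.ndarray) -> np.ndarray:
            return model.predict(images)

        predict.history = history  # type: ignore[attr-defined]
        predict.model = model  # type: ignore[attr-defined]
        return predict

    return trainer


@dataclass
class ExperimentResult:
    confusion: ConfusionMatrix
    report: MetricsReport
    fold_matrices: dict[str, ConfusionMatrix] = field(default_factory=dict)
    fold_reports: dict[str, MetricsReport] = field(default_factory=dict)


def run_cross_dataset(
    train_ds: BeatDataset,
    test_ds: BeatDataset,
    cfg: TrainConfig,
    trainer: Trainer | None = None,
    model_spec: ResNetSpec | None = None,
) -> ExperimentResult:
    """Train on one dataset, test on another with disjoint subjects."""
    overlap = train_ds.subject_ids & test_ds.subject_ids
    if overlap:
        raise ValueError(
            f"train/test subject ids overlap (leakage): {sorted(overlap)}"
        )
    trainer = trainer or default_trainer(model_spec)
    predict = trainer(train_ds, cfg, test_ds.subject_ids)
    pred = np.asarray(predict(test_ds.images))
    cm = confusion(test_ds.labels, pred)
    return ExperimentResult(cm, metrics(cm))


def run_losocv(
    dataset: BeatDataset,
    cfg: TrainConfig,
    trainer: Trainer | None = None,
    model_spec: ResNetSpec | None = None,
) -> ExperimentResult:
    """Leave-one-subject-out CV: each subject is the test fold exactly once."""
    subjects = sorted(dataset.subject_ids)
    if len(subjects) < 2:
        raise ValueError(f"LOSOCV needs >= 2 subjects, got {len(subjects)}")
    trainer = trainer or default_trainer(model_spec)
    fold_matrices: dict[str, ConfusionMatrix] = {}
    fold_reports: dict[str, MetricsReport] = {}
    agg = ConfusionMatrix(0, 0, 0, 0)
    for subj in subjects:
        test_mask = dataset.subjects.astype(str) == subj
        test_ds = dataset.subset(np.where(test_mask)[0])
        train_ds = dataset.subset(np.where(~test_mask)[0])
        predict = trainer(train_ds, cfg, {subj})
        pred = np.asarray(predict(test_ds.images))
        cm = confusion(test_ds.labels, pred)
        fold_matrices[subj] = cm
        fold_reports[subj] = metrics(cm)
        agg = agg + cm
    return ExperimentResult(agg, metrics(agg), fold_matrices, fold_reports)


def run_holdout(
    dataset: BeatDataset,
    cfg: TrainConfig,
    test_fraction: float = 0.2,
    seed: int = 0,
    trainer: Trainer | None = None,
    model_spec: ResNetSpec | None = None,
) -> ExperimentResult:
    """Random beat-level hold-out split (no subject separation)."""
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, shuffle=True
    )
    trainer = trainer or default_trainer(model_spec)
    train_ds, test_ds = dataset.subset(train_idx), dataset.subset(test_idx)
    predict = trainer(train_ds, cfg, set())
    pred = np.asarray(predict(test_ds.images))
    cm = confusion(test_ds.labels, pred)
    return ExperimentResult(cm, metrics(cm))


def run_stratified_kfold(
    dataset: BeatDataset,
    cfg: TrainConfig,
    k: int = 10,
    seed: int = 0,
    trainer: Trainer | None = None,
    model_spec: ResNetSpec | None = None,
) -> ExperimentResult:
    """Beat-level stratified k-fold; folds preserve class proportions."""
    if k < 2:
        raise ValueError("k must be >= 2")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    trainer = trainer or default_trainer(model_spec)
    agg = ConfusionMatrix(0, 0, 0, 0)
    fold_matrices: dict[str, ConfusionMatrix] = {}
    for f, (train_idx, test_idx) in enumerate(skf.split(dataset.images, dataset.labels)):
        test_ds = dataset.subset(test_idx)
        assert len(np.unique(test_ds.labels)) == 2, "stratification must keep both classes"
        predict = trainer(dataset.subset(train_idx), cfg, set())
        pred = np.asarray(predict(test_ds.images))
        cm = confusion(test_ds.labels, pred)
        fold_matrices[f"fold{f}"] = cm
        agg = agg + cm
    return ExperimentResult(agg, metrics(agg), fold_matrices)
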