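"""End-to-end pipelines wiring conditioning, segmentation, features,
selection and cross-validation for the two tasks.

Quality task:   filter -> phase windows -> item features -> (CFS) -> LOSO.
Detection task: filter -> sliding windows -> 59 features -> 1:1 rebalance
                -> (CFS) -> LOSO.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .detection import extract_detection_features
from .errors import ConfigError
from .evaluation import CVResult, rebalance, run_cv
from .featurematrix import FeatureMatrix
from .quality import build_quality_matrix
from .segmentation import (
    DETECTION_HOP,
    DETECTION_WIDTH,
    TransferAnnotation,
    extract_phase_windows,
    label_windows,
    slide_windows,
)
from .selection import SelectionResult, cfs_select
from .signal import AccelerometerRecording, lowpass_filter

CFS_MODES = ("off", "global", "per_fold")

CONTROLLED_FLIGHT_NOTICE = (
    "controlled-flight evaluation is disabled by default: dichotomous labels "
    "for this item are typically far too imbalanced to train a classifier on "
    "(nearly every transfer is rated good). Features are still computed and "
    "exportable; pass force=True to train anyway."
)


def _by_subject(recordings: Sequence[AccelerometerRecording]) -> dict:
    return {rec.subject_id: rec for rec in recordings}


def filter_recordings(
    recordings: Sequence[AccelerometerRecording], order: int = 8, cutoff: float = 10.0
) -> list[AccelerometerRecording]:
    return [lowpass_filter(rec, order=order, cutoff=cutoff) for rec in recordings]


def quality_feature_matrix(
    recordings: Sequence[AccelerometerRecording],
    annotations: Sequence[TransferAnnotation],
    item: str,
    prefiltered: bool = False,
) -> FeatureMatrix:
    """Phase-window feature matrix for one quality item across all transfers."""
    recs = recordings if prefiltered else filter_recordings(recordings)
    by_subject = _by_subject(recs)
    windows = []
    for ann in annotations:
        if ann.subject_id not in by_subject:
            raise ConfigError(f"{ann.transfer_id}: no recording for subject {ann.subject_id}")
        windows.append(extract_phase_windows(by_subject[ann.subject_id], ann))
    return build_quality_matrix(windows, annotations, item)


def detection_feature_matrix(
    recordings: Sequence[AccelerometerRecording],
    annotations: Sequence[TransferAnnotation],
    width: int = DETECTION_WIDTH,
    hop: int = DETECTION_HOP,
    prefiltered: bool = False,
) -> FeatureMatrix:
    """Labeled 59-feature matrix over sliding windows of all recordings."""
    recs = recordings if prefiltered else filter_recordings(recordings)
    parts = []
    for rec in recs:
        anns = [a for a in annotations if a.subject_id == rec.subject_id]
        windows = label_windows(slide_windows(rec, width, hop), anns, rec.fs, rec.t0)
        parts.append(extract_detection_features(rec, windows))
    first = parts[0]
    return FeatureMatrix(
        feature_names=list(first.feature_names),
        X=np.vstack([p.X for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        groups=np.concatenate([p.groups for p in parts]),
        row_ids=[rid for p in parts for rid in p.row_ids],
    )


@dataclass
class PipelineResult:
    cv: CVResult
    selection: SelectionResult | None
    matrix: FeatureMatrix


def _apply_cfs(fm: FeatureMatrix, cfs: str, seed: int):
    """Returns (matrix-to-train-on, SelectionResult|None, per-fold selector|None)."""
    if cfs not in CFS_MODES:
        raise ConfigError(f"cfs mode must be one of {CFS_MODES}")
    if cfs == "off":
        return fm, None, None
    if cfs == "global":
        sel = cfs_select(fm)
        return fm.select_features(sel.selected), sel, None
    return fm, None, lambda train_fm: cfs_select(train_fm).selected


def evaluate_quality(
    recordings: Sequence[AccelerometerRecording],
    annotations: Sequence[TransferAnnotation],
    item: str,
    classifier: str = "svm",
    seed: int = 0,
    cfs: str = "off",
    config: dict | None = None,
    force: bool = False,
    prefiltered: bool = False,
) -> PipelineResult:
    """Full quality pipeline for one item and one classifier family."""
    if item == "controlled_flight" and not force:
        raise ConfigError(CONTROLLED_FLIGHT_NOTICE)
    fm = quality_feature_matrix(recordings, annotations, item, prefiltered=prefiltered)
    fm_used, sel, selector = _apply_cfs(fm, cfs, seed)
    cv = run_cv(fm_used, classifier=classifier, seed=seed, config=config,
                feature_selector=selector)
    return PipelineResult(cv=cv, selection=sel, matrix=fm)


def evaluate_detection(
    recordings: Sequence[AccelerometerRecording],
    annotations: Sequence[TransferAnnotation],
    classifier: str = "svm",
    seed: int = 0,
    cfs: str = "off",
    rebalance_classes: bool = True,
    config: dict | None = None,
    prefiltered: bool = False,
    matrix: FeatureMatrix | None = None,
) -> PipelineResult:
    """Full detection pipeline; ``matrix`` may be passed to reuse extracted
    features across classifier families."""
    fm = (
        matrix
        if matrix is not None
        else detection_feature_matrix(recordings, annotations, prefiltered=prefiltered)
    )
    fm_used = rebalance(fm, seed=seed) if rebalance_classes else fm
    fm_used, sel, selector = _apply_cfs(fm_used, cfs, seed)
    cv = run_cv(fm_used, classifier=classifier, seed=seed, config=config,
                feature_selector=selector)
    return PipelineResult(cv=cv, selection=sel, matrix=fm)
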