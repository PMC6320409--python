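"""Candidate features for transfer-quality evaluation.

Three aspects of transfer technique are scored from phase windows:

* **head-hip relationship** — a correct transfer starts with a quick, deep
  forward trunk lean (head opposite the hips), producing a sharp dip in the
  frontal (Z) acceleration and in its jerk;
* **controlled flight** — a smooth, coordinated pivot between surfaces,
  quantified by spectral arc length and dimensionless-jerk smoothness of the
  reconstructed speed profile;
* **smooth landing** — a controlled descent, i.e. a small vertical impact
  spike, versus a hard landing with a large one.

The *frontal-downward* composite signal approximates acceleration along the
lean direction: the vertical axis plus the sign-inverted frontal axis
(``x - z``). Sign inversion, not reciprocal, is the only dimensionally
meaningful reading of combining "vertical" with "inverse frontal".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import ConfigError, DegenerateSignalError
from .featurematrix import FeatureMatrix
from .segmentation import AxisTriple, PhaseWindows
from .signal import SignalSeries, jerk, total_acceleration
from .smoothness import dimensionless_jerk, sparc

HEAD_HIP_FEATURES = (
    "min_frontal_acc",
    "min_frontal_jerk",
    "max_total_jerk",
    "range_frontal_acc",
    "max_frontal_downward_acc",
    "range_frontal_downward_acc",
)

FLIGHT_FEATURES = (
    "sparc_acc",
    "sparc_vel",
    "dimensionless_jerk",
    "log_dimensionless_jerk",
)

LANDING_FEATURES = (
    "max_vertical_acc",
    "max_total_acc",
    "mean_total_acc",
    "mean_vertical_acc",
    "rms_total_acc",
    "range_total_acc",
)


@dataclass(frozen=True)
class QualityFeatureVector:
    phase: str
    features: Mapping[str, float]
    transfer_id: str

    def __post_init__(self) -> None:
        expected = {
            "head_hip": HEAD_HIP_FEATURES,
            "flight": FLIGHT_FEATURES,
            "landing": LANDING_FEATURES,
        }[self.phase]
        if tuple(self.features.keys()) != expected:
            raise ConfigError(f"{self.phase} features must be {expected} in order")
        vals = np.asarray(list(self.features.values()), dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ConfigError(f"{self.transfer_id}: non-finite {self.phase} feature")


def frontal_downward(x, z) -> np.ndarray:
    """Composite lean-direction signal: vertical plus sign-inverted frontal."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ConfigError("x and z slices must have the same length")
    return x - z


def head_hip_features(pw: PhaseWindows) -> QualityFeatureVector:
    """Extrema/range features of the head-hip window (frontal dip and jerk)."""
    w = pw.head_hip
    if len(w.z) < 2:
        raise DegenerateSignalError("insufficient samples for jerk in head-hip window")
    z = SignalSeries(w.z, pw.fs)
    tot = total_acceleration((w.x, w.y, w.z, pw.fs))
    fd = frontal_downward(w.x, w.z)
    feats = {
        "min_frontal_acc": float(np.min(w.z)),
        "min_frontal_jerk": float(np.min(jerk(z).values)),
        "max_total_jerk": float(np.max(jerk(tot).values)),
        "range_frontal_acc": float(np.max(w.z) - np.min(w.z)),
        "max_frontal_downward_acc": float(np.max(fd)),
        "range_frontal_downward_acc": float(np.max(fd) - np.min(fd)),
    }
    return QualityFeatureVector("head_hip", feats, pw.source)


def landing_features(pw: PhaseWindows) -> QualityFeatureVector:
    """Impact-magnitude features of the landing window."""
    w = pw.landing
    tot = total_acceleration((w.x, w.y, w.z, pw.fs)).values
    feats = {
        "max_vertical_acc": float(np.max(w.x)),
        "max_total_acc": float(np.max(tot)),
        "mean_total_acc": float(np.mean(tot)),
        "mean_vertical_acc": float(np.mean(w.x)),
        "rms_total_acc": float(np.sqrt(np.mean(tot * tot))),
        "range_total_acc": float(np.max(tot) - np.min(tot)),
    }
    return QualityFeatureVector("landing", feats, pw.source)


def _speed_profile(w: AxisTriple, fs: float) -> np.ndarray:
    """Speed reconstructed by per-axis mean removal (crude gravity removal)
    and cumulative trapezoidal integration. Windows are short (a few seconds)
    so the residual linear drift from mean removal is tolerated."""
    vel = [
        cumulative_trapezoid(np.asarray(a, float) - np.mean(a), dx=1.0 / fs, initial=0.0)
        for a in (w.x, w.y, w.z)
    ]
    return np.sqrt(sum(v * v for v in vel))


def flight_smoothness(pw: PhaseWindows) -> QualityFeatureVector:
    """Smoothness features of the flight window (SPARC and dimensionless jerk)."""
    w = pw.flight
    if len(w.x) < 8:
        raise DegenerateSignalError("flight window too short (need >= 8 samples)")
    tot = total_acceleration((w.x, w.y, w.z, pw.fs)).values
    speed = _speed_profile(w, pw.fs)
    dj, ldj = dimensionless_jerk(speed, pw.fs)
    feats = {
        "sparc_acc": sparc(tot, pw.fs),
        "sparc_vel": sparc(speed, pw.fs) if np.any(speed) else _degenerate(pw),
        "dimensionless_jerk": dj,
        "log_dimensionless_jerk": ldj,
    }
    return QualityFeatureVector("flight", feats, pw.source)


def _degenerate(pw: PhaseWindows) -> float:
    raise DegenerateSignalError(f"{pw.source}: degenerate flight speed profile")


_PHASE_OF_ITEM = {
    "head_hip": ("head_hip", head_hip_features, HEAD_HIP_FEATURES),
    "controlled_flight": ("flight", flight_smoothness, FLIGHT_FEATURES),
    "smooth_landing": ("landing", landing_features, LANDING_FEATURES),
}


def build_quality_matrix(phase_windows, annotations, item: str) -> FeatureMatrix:
    """Assemble the per-transfer feature matrix for one quality item.

    ``phase_windows`` and ``annotations`` are parallel sequences; the class
    label is the annotation's dichotomous score for ``item``.
    """
    if item not in _PHASE_OF_ITEM:
        raise ConfigError(f"unknown quality item {item!r}")
    _, fn, names = _PHASE_OF_ITEM[item]
    rows, labels, groups, ids = [], [], [], []
    for pw, ann in zip(phase_windows, annotations):
        if item not in ann.labels:
            raise ConfigError(f"{ann.transfer_id}: no label for item {item}")
        vec = fn(pw)
        rows.append([vec.features[n] for n in names])
        labels.append(ann.labels[item])
        groups.append(ann.subject_id)
        ids.append(ann.transfer_id)
    return FeatureMatrix(
        feature_names=list(names),
        X=np.asarray(rows),
        labels=np.asarray(labels, dtype=object),
        groups=np.asarray(groups, dtype=object),
        row_ids=ids,
    )
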