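"""Phase windows around annotated seat-off/landing and sliding detection windows.

A transfer is bounded by two video-annotated timestamps: *start of lift*
(buttocks leave the initial surface) and *landing* (buttocks contact the
target surface). Quality evaluation cuts three epochs around them:

* head-hip phase: +/-0.75 s around start of lift,
* flight phase:   start of lift -0.5 s to landing +0.5 s,
* landing phase:  +/-0.75 s around landing.

Detection uses 25-sample (1 s at 25 Hz) windows with roughly 50% overlap
(hop 12 samples; 12.5 is non-integral, flooring keeps the grid integral and
every sample covered).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError, SegmentationError
from .signal import AccelerometerRecording

log = logging.getLogger(__name__)

SCENARIOS = ("bed", "toilet", "car")
DIRECTIONS = ("to_wheelchair", "from_wheelchair")
QUALITY_ITEMS = ("head_hip", "controlled_flight", "smooth_landing")
QUALITY_LABELS = ("good", "not_good")

HEAD_HIP_HALF_S = 0.75
LANDING_HALF_S = 0.75
FLIGHT_MARGIN_S = 0.5

DETECTION_WIDTH = 25
DETECTION_HOP = 12

ANNOTATION_COLUMNS = [
    "transfer_id",
    "subject_id",
    "scenario",
    "direction",
    "start_lift",
    "landing",
    "head_hip",
    "controlled_flight",
    "smooth_landing",
]


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


@dataclass(frozen=True)
class TransferAnnotation:
    """One transfer's timestamps, scenario, direction and dichotomous labels."""

    transfer_id: str
    subject_id: str
    scenario: str
    direction: str
    start_lift: float
    landing: float
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"{self.transfer_id}: unknown scenario {self.scenario!r}")
        if self.direction not in DIRECTIONS:
            raise ConfigError(f"{self.transfer_id}: unknown direction {self.direction!r}")
        if not self.start_lift < self.landing:
            raise ConfigError(
                f"{self.transfer_id}: start_lift ({self.start_lift}) must precede "
                f"landing ({self.landing})"
            )
        for item, lab in self.labels.items():
            if item not in QUALITY_ITEMS or lab not in QUALITY_LABELS:
                raise ConfigError(
                    f"{self.transfer_id}: invalid label {item}={lab!r} "
                    f"(items {QUALITY_ITEMS}, values {QUALITY_LABELS})"
                )


class AxisTriple(NamedTuple):
    """Aligned x/y/z slices of a recording."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray


@dataclass(frozen=True)
class PhaseWindows:
    """The three per-transfer sample windows cut around seat-off and landing."""

    head_hip: AxisTriple
    flight: AxisTriple
    landing: AxisTriple
    fs: float
    source: str


@dataclass(frozen=True)
class DetectionWindow:
    """One sliding window for transfer-occurrence detection."""

    start_index: int
    width: int
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    label: str | None = None


def _slice_triple(rec: AccelerometerRecording, lo: int, hi: int) -> AxisTriple:
    """Inclusive [lo, hi] copy of all three axes."""
    return AxisTriple(
        rec.x[lo : hi + 1].copy(), rec.y[lo : hi + 1].copy(), rec.z[lo : hi + 1].copy()
    )


def extract_phase_windows(
    rec: AccelerometerRecording, ann: TransferAnnotation
) -> PhaseWindows:
    """Cut head-hip, flight and landing windows for one annotated transfer.

    Index conversion is round-half-up, so +/-0.75 s at 25 Hz yields a
    half-width of 19 samples (39-sample inclusive window) and the +/-0.5 s
    flight margin a half-width of 13. Slices are copies, not views.
    """
    c_lift = rec.index_of(ann.start_lift)
    c_land = rec.index_of(ann.landing)
    hh_half = _round_half_up(HEAD_HIP_HALF_S * rec.fs)
    ld_half = _round_half_up(LANDING_HALF_S * rec.fs)
    fl_half = _round_half_up(FLIGHT_MARGIN_S * rec.fs)
    bounds = {
        "head_hip": (c_lift - hh_half, c_lift + hh_half),
        "flight": (c_lift - fl_half, c_land + fl_half),
        "landing": (c_land - ld_half, c_land + ld_half),
    }
    windows = {}
    for phase, (lo, hi) in bounds.items():
        if lo < 0 or hi >= rec.n_samples:
            raise SegmentationError(
                f"annotation {ann.transfer_id} too close to recording edge "
                f"({phase} window [{lo}, {hi}] outside [0, {rec.n_samples - 1}])"
            )
        windows[phase] = _slice_triple(rec, lo, hi)
    return PhaseWindows(
        head_hip=windows["head_hip"],
        flight=windows["flight"],
        landing=windows["landing"],
        fs=rec.fs,
        source=ann.transfer_id,
    )


def slide_windows(
    rec: AccelerometerRecording,
    width: int = DETECTION_WIDTH,
    hop: int = DETECTION_HOP,
) -> list[DetectionWindow]:
    """Enumerate full windows starting at 0, hop, 2*hop, ... (no partials)."""
    n = rec.n_samples
    if n < width:
        raise SegmentationError(f"recording too short ({n} samples < width {width})")
    out = []
    for start in range(0, n - width + 1, hop):
        out.append(
            DetectionWindow(
                start_index=start,
                width=width,
                x=rec.x[start : start + width].copy(),
                y=rec.y[start : start + width].copy(),
                z=rec.z[start : start + width].copy(),
            )
        )
    return out


def label_windows(
    windows: Sequence[DetectionWindow],
    anns: Iterable[TransferAnnotation],
    fs: float,
    t0: float = 0.0,
) -> list[DetectionWindow]:
    """Label each window ``transfer`` iff it overlaps any [start_lift, landing]
    interval by at least one sample, else ``no_transfer``.

    Overlapping annotation intervals are unioned (with a logged warning).
    """
    intervals = []
    for ann in anns:
        lo = _round_half_up((ann.start_lift - t0) * fs)
        hi = _round_half_up((ann.landing - t0) * fs)
        intervals.append((lo, hi))
    intervals.sort()
    for (a_lo, a_hi), (b_lo, b_hi) in zip(intervals, intervals[1:]):
        if b_lo <= a_hi:
            log.warning(
                "overlapping transfer intervals [%d,%d] and [%d,%d]; using union",
                a_lo,
                a_hi,
                b_lo,
                b_hi,
            )
    out = []
    for w in windows:
        w_lo, w_hi = w.start_index, w.start_index + w.width - 1
        hit = any(lo <= w_hi and hi >= w_lo for lo, hi in intervals)
        out.append(replace(w, label="transfer" if hit else "no_transfer"))
    return out


def read_annotations(path) -> list[TransferAnnotation]:
    """Read the one-row-per-transfer annotations CSV."""
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing annotation columns {missing}")
    anns = []
    for _, row in df.iterrows():
        anns.append(
            TransferAnnotation(
                transfer_id=str(row["transfer_id"]),
                subject_id=str(row["subject_id"]),
                scenario=str(row["scenario"]),
                direction=str(row["direction"]),
                start_lift=float(row["start_lift"]),
                landing=float(row["landing"]),
                labels={
                    item: str(row[item])
                    for item in QUALITY_ITEMS
                    if isinstance(row[item], str) or not pd.isna(row[item])
                },
            )
        )
    return anns


def write_annotations(anns: Sequence[TransferAnnotation], path) -> None:
    rows = []
    for a in anns:
        row = {
            "transfer_id": a.transfer_id,
            "subject_id": a.subject_id,
            "scenario": a.scenario,
            "direction": a.direction,
            "start_lift": a.start_lift,
            "landing": a.landing,
        }
        for item in QUALITY_ITEMS:
            row[item] = a.labels.get(item, "")
        rows.append(row)
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)
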