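"""Synthetic multi-subject transfer sessions with ground-truth annotations.

The generator emulates the study protocol: each subject wears a chest
accelerometer for about 40 minutes and performs 12 transfers (2 return
transfers in each of 3 scenarios: bed, toilet, car) separated by at least a
minute of rest, with wheelchair-propulsion bursts in between.

Signals are modeled in the sensor frame *including* the gravity projection,
as a real chest accelerometer measures: upright, the vertical axis X reads
+1 g; a forward trunk lean of pitch angle theta re-orients gravity so that
X = cos(theta) and the frontal axis Z = -sin(theta). The quality items act
on disjoint aspects of the waveform so each is independently recoverable:

* head-hip relationship — good transfers use a faster, deeper lean (larger
  frontal dip and dip jerk);
* controlled flight — bad transfers get a superimposed 8 Hz oscillation
  during the flight segment;
* smooth landing — the landing is a decaying ~6 Hz sinusoid impact surrogate
  on X whose peak amplitude encodes landing hardness.

Between-subject variability comes from a fixed per-subject torso tilt (up to
10 degrees) and movement-amplitude scaling (+/-20%), which keeps
leave-one-subject-out evaluation non-trivial without modeling anthropometry.
The full dataset is a pure, bit-reproducible function of the configuration
(including its seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .segmentation import (
    DETECTION_HOP,
    DETECTION_WIDTH,
    SCENARIOS,
    TransferAnnotation,
    label_windows,
    slide_windows,
    write_annotations,
)
from .signal import AccelerometerRecording, write_recording


@dataclass(frozen=True)
class SimulationConfig:
    """Study-protocol conditions and effect sizes for the generator."""

    n_subjects: int = 9
    fs: float = 25.0
    session_minutes: float = 40.0
    transfers_per_subject: int = 12
    rest_gap_s: float = 60.0
    #: peak forward-pitch amplitude of the lean, degrees
    lean_amp_good: float = 55.0
    lean_amp_bad: float = 18.0
    #: lean rise time, s (good = faster and deeper)
    lean_dur_good: float = 0.7
    lean_dur_bad: float = 1.4
    #: landing impulse peak amplitude, g
    landing_peak_smooth: float = 1.2
    landing_peak_hard: float = 2.0
    flight_ripple_hz: float = 8.0
    flight_ripple_amp: float = 1.0
    noise_sd: float = 0.05
    #: per-item probability that a transfer is performed "good"
    quality_prob: float = 0.5
    subject_tilt_max_deg: float = 10.0
    subject_scale_range: float = 0.2
    flight_dur_s: float = 1.2
    flight_dur_jitter_s: float = 0.2
    event_len_s: float = 5.0
    edge_margin_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        for name in (
            "lean_amp_good",
            "lean_amp_bad",
            "landing_peak_smooth",
            "landing_peak_hard",
            "flight_ripple_amp",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.quality_prob <= 1:
            raise ConfigError("quality_prob must be in [0, 1]")
        if self.flight_dur_jitter_s >= self.flight_dur_s:
            raise ConfigError("flight duration jitter must be below the mean duration")
        n = self.transfers_per_subject
        if n > 0:
            needed = (
                2 * self.edge_margin_s
                + n * self.event_len_s
                + (n - 1) * self.rest_gap_s
            )
            if needed > self.session_minutes * 60.0:
                raise ConfigError(
                    f"{n} transfers with {self.rest_gap_s:g} s rest gaps do not fit "
                    f"in a {self.session_minutes:g}-minute session; lengthen the session"
                )


@dataclass(frozen=True)
class SimulatedDataset:
    """Generated recordings plus ground-truth annotations."""

    recordings: tuple[AccelerometerRecording, ...]
    annotations: tuple[TransferAnnotation, ...]
    config: SimulationConfig

    def annotations_for(self, subject_id: str) -> list[TransferAnnotation]:
        return [a for a in self.annotations if a.subject_id == subject_id]


_LANDING_FREQ_HZ = 6.0
_LANDING_DECAY_S = 0.15
_LEAN_ONSET_S = 0.8
_RETURN_DUR_S = 0.8
_POST_LANDING_HOLD_S = 0.3


def simulate_transfer_event(
    config: SimulationConfig,
    rng: np.random.Generator,
    good_head_hip: bool = True,
    good_flight: bool = True,
    good_landing: bool = True,
    scale: float = 1.0,
    tilt_deg: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """One transfer segment in the sensor frame (noise-free).

    Returns ``(x, y, z, start_lift_offset, landing_offset)`` with offsets in
    seconds from the start of the segment.
    """
    fs = config.fs
    n = int(round(config.event_len_s * fs))
    t = np.arange(n) / fs

    # event-to-event execution variability: depth and speed of the lean vary
    # independently (+/-10%) so derived features are not artificially collinear
    amp_jit = float(rng.uniform(0.9, 1.1))
    dur_jit = float(rng.uniform(0.9, 1.1))
    lean_amp = (config.lean_amp_good if good_head_hip else config.lean_amp_bad) * scale * amp_jit
    lean_dur = (config.lean_dur_good if good_head_hip else config.lean_dur_bad) * dur_jit
    start_lift = _LEAN_ONSET_S + 0.7 * lean_dur
    flight_dur = config.flight_dur_s + float(
        rng.uniform(-config.flight_dur_jitter_s, config.flight_dur_jitter_s)
    )
    landing = start_lift + flight_dur
    if landing <= start_lift:
        raise ConfigError("landing before seat-off (check flight duration)")
    tail = landing + _POST_LANDING_HOLD_S + _RETURN_DUR_S
    if tail >= config.event_len_s:
        raise ConfigError(
            f"event does not fit: needs {tail:.2f} s, segment is {config.event_len_s:g} s"
        )

    # bell-shaped lean-and-return pitch trajectory (degrees)
    theta = np.zeros(n)
    # optional momentum-gathering backswing (slight backward trunk motion
    # before the forward lean); independent of every quality flag
    if rng.random() < 0.6:
        back_amp = float(rng.uniform(4.0, 12.0)) * scale
        back = (t >= _LEAN_ONSET_S - 0.5) & (t < _LEAN_ONSET_S)
        theta[back] -= back_amp * np.sin(np.pi * (t[back] - _LEAN_ONSET_S + 0.5) / 0.5) ** 2
    rise = (t >= _LEAN_ONSET_S) & (t < _LEAN_ONSET_S + lean_dur)
    theta[rise] = lean_amp * 0.5 * (1 - np.cos(np.pi * (t[rise] - _LEAN_ONSET_S) / lean_dur))
    hold = (t >= _LEAN_ONSET_S + lean_dur) & (t < landing + _POST_LANDING_HOLD_S)
    theta[hold] = lean_amp
    fall = (t >= landing + _POST_LANDING_HOLD_S) & (
        t < landing + _POST_LANDING_HOLD_S + _RETURN_DUR_S
    )
    theta[fall] = lean_amp * 0.5 * (
        1 + np.cos(np.pi * (t[fall] - landing - _POST_LANDING_HOLD_S) / _RETURN_DUR_S)
    )

    ang = np.radians(theta + tilt_deg)
    x = np.cos(ang)
    z = -np.sin(ang)
    y = np.zeros(n)

    # lateral pivot swing during flight
    in_flight = (t >= start_lift) & (t <= landing)
    tf = (t[in_flight] - start_lift) / flight_dur
    swing_sign = 1.0 if rng.random() < 0.5 else -1.0
    y[in_flight] += swing_sign * 0.25 * scale * np.sin(np.pi * tf) ** 2

    if not good_flight:
        # lateral axis only: keeps the flight flag out of the head-hip (Z)
        # and landing (X) feature windows, so the items stay independently
        # recoverable; flight smoothness sees it via speed and total acceleration
        env = np.sin(np.pi * tf) ** 2
        rip = config.flight_ripple_amp * scale * np.sin(
            2 * np.pi * config.flight_ripple_hz * (t[in_flight] - start_lift)
        )
        y[in_flight] += rip * env

    # landing impact: decaying sinusoid normalized to its peak
    peak = (config.landing_peak_smooth if good_landing else config.landing_peak_hard) * scale
    after = t >= landing
    tau = t[after] - landing
    pat = np.exp(-tau / _LANDING_DECAY_S) * np.sin(2 * np.pi * _LANDING_FREQ_HZ * tau)
    m = np.max(np.abs(pat))
    if m > 0:
        pat = pat / m
    x[after] += peak * pat
    y[after] += 0.3 * peak * pat

    return x, y, z, start_lift, landing


def _event_starts(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.transfers_per_subject
    total = config.session_minutes * 60.0
    pitch = config.event_len_s + config.rest_gap_s
    needed = 2 * config.edge_margin_s + n * config.event_len_s + (n - 1) * config.rest_gap_s
    slack = total - needed
    offsets = np.sort(rng.uniform(0.0, slack, size=n))
    return config.edge_margin_s + offsets + np.arange(n) * pitch


def simulate_session(
    config: SimulationConfig, subject_index: int
) -> tuple[AccelerometerRecording, list[TransferAnnotation]]:
    """One subject's continuous session: rest + propulsion background with
    the configured number of transfer events embedded at randomized times."""
    rng = np.random.default_rng([config.seed, subject_index])
    subject_id = f"S{subject_index + 1:02d}"
    tilt = float(rng.uniform(0.0, config.subject_tilt_max_deg))
    scale = float(rng.uniform(1 - config.subject_scale_range, 1 + config.subject_scale_range))

    n = int(round(config.session_minutes * 60.0 * config.fs))
    tilt_rad = np.radians(tilt)
    x = np.full(n, np.cos(tilt_rad))
    y = np.zeros(n)
    z = np.full(n, -np.sin(tilt_rad))

    anns: list[TransferAnnotation] = []
    starts = _event_starts(config, rng) if config.transfers_per_subject > 0 else np.array([])
    event_spans: list[tuple[float, float]] = []
    n_ev = len(starts)
    for i, t_start in enumerate(starts):
        good = {item: bool(rng.random() < config.quality_prob) for item in
                ("head_hip", "controlled_flight", "smooth_landing")}
        ex, ey, ez, off_lift, off_land = simulate_transfer_event(
            config,
            rng,
            good_head_hip=good["head_hip"],
            good_flight=good["controlled_flight"],
            good_landing=good["smooth_landing"],
            scale=scale,
            tilt_deg=tilt,
        )
        s = int(round(t_start * config.fs))
        e = s + len(ex)
        x[s:e], y[s:e], z[s:e] = ex, ey, ez
        event_spans.append((t_start, t_start + config.event_len_s))
        scenario = SCENARIOS[min(i * 3 // max(n_ev, 1), 2)]
        direction = ("from_wheelchair", "to_wheelchair")[i % 2]
        anns.append(
            TransferAnnotation(
                transfer_id=f"{subject_id}-T{i + 1:02d}",
                subject_id=subject_id,
                scenario=scenario,
                direction=direction,
                start_lift=t_start + off_lift,
                landing=t_start + off_land,
                labels={k: ("good" if v else "not_good") for k, v in good.items()},
            )
        )

    # wheelchair-propulsion bursts in the gaps between events
    gap_starts = [0.0] + [e for _, e in event_spans]
    gap_ends = [s for s, _ in event_spans] + [config.session_minutes * 60.0]
    for g_lo, g_hi in zip(gap_starts, gap_ends):
        if rng.random() > 0.7:
            continue
        dur = float(rng.uniform(5.0, 12.0))
        lo, hi = g_lo + 2.0, g_hi - 2.0 - dur
        if hi <= lo:
            continue
        b0 = float(rng.uniform(lo, hi))
        i0, i1 = int(round(b0 * config.fs)), int(round((b0 + dur) * config.fs))
        tb = np.arange(i1 - i0) / config.fs
        freq = float(rng.uniform(2.0, 3.0))
        phase = float(rng.uniform(0, 2 * np.pi))
        osc = np.sin(2 * np.pi * freq * tb + phase)
        env = np.sin(np.pi * tb / dur) ** 2
        z[i0:i1] += 0.12 * scale * osc * env
        y[i0:i1] += 0.08 * scale * np.sin(2 * np.pi * freq * tb + phase + 1.1) * env
        x[i0:i1] += 0.03 * scale * osc * env

    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, n)
        y = y + rng.normal(0.0, config.noise_sd, n)
        z = z + rng.normal(0.0, config.noise_sd, n)

    rec = AccelerometerRecording(subject_id=subject_id, fs=config.fs, x=x, y=y, z=z)
    return rec, anns


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """All subjects' sessions plus their ground-truth annotations."""
    recordings = []
    annotations = []
    for i in range(config.n_subjects):
        rec, anns = simulate_session(config, i)
        recordings.append(rec)
        annotations.extend(anns)
    return SimulatedDataset(
        recordings=tuple(recordings), annotations=tuple(annotations), config=config
    )


def positive_window_fraction(
    ds: SimulatedDataset, width: int = DETECTION_WIDTH, hop: int = DETECTION_HOP
) -> float:
    """Fraction of detection windows overlapping a transfer (class imbalance)."""
    pos = tot = 0
    for rec in ds.recordings:
        windows = label_windows(
            slide_windows(rec, width, hop),
            ds.annotations_for(rec.subject_id),
            rec.fs,
            rec.t0,
        )
        pos += sum(1 for w in windows if w.label == "transfer")
        tot += len(windows)
    return pos / tot


def config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_dataset(ds: SimulatedDataset, outdir) -> dict:
    """Write per-subject signal CSVs, the annotations CSV, truth.json and a
    manifest with the configuration hash. Returns the manifest dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in ds.recordings:
        write_recording(rec, out / f"{rec.subject_id}.csv")
    write_annotations(list(ds.annotations), out / "annotations.csv")

    truth = {}
    for rec in ds.recordings:
        windows = label_windows(
            slide_windows(rec), ds.annotations_for(rec.subject_id), rec.fs, rec.t0
        )
        truth[rec.subject_id] = {
            "n_windows": len(windows),
            "n_positive": sum(1 for w in windows if w.label == "transfer"),
            "windows": [
                {"start_index": w.start_index, "label": w.label} for w in windows
            ],
        }
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)
    manifest = {
        "config": asdict(ds.config),
        "config_hash": config_hash(ds.config),
        "subjects": [rec.subject_id for rec in ds.recordings],
        "n_annotations": len(ds.annotations),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
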