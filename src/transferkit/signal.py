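"""Triaxial chest-accelerometer data model, file I/O and signal conditioning.

The sensor is worn on the upper sternum and reports acceleration in g-units
along body axes: X vertical (+up/-down), Y lateral (+left/-right), Z frontal
(+front/-back). Recordings are uniformly sampled (25 Hz nominal) and bounded
by the sensor range of +/-16 g. All downstream feature computations assume a
single low-pass conditioning pass applied to the full recording before any
segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _sps

from .errors import ConfigError, DegenerateSignalError, ParseError

SENSOR_RANGE_G = 16.0

#: relative timing jitter tolerated before a recording is declared non-uniform
JITTER_TOL = 0.01


@dataclass(frozen=True)
class AccelerometerRecording:
    """Uniformly sampled triaxial trunk acceleration in g-units.

    Sample index ``i`` maps to time ``t0 + i / fs``.
    """

    subject_id: str
    fs: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        for axis in ("x", "y", "z"):
            arr = np.asarray(getattr(self, axis), dtype=float)
            object.__setattr__(self, axis, arr)
        if not self.fs > 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        n = len(self.x)
        if n < 2 or len(self.y) != n or len(self.z) != n:
            raise ConfigError(
                "axis sequences must have identical length >= 2 "
                f"(got {len(self.x)}, {len(self.y)}, {len(self.z)})"
            )
        for axis in ("x", "y", "z"):
            arr = getattr(self, axis)
            if not np.all(np.isfinite(arr)):
                raise ConfigError(f"non-finite samples on axis {axis}")
            if np.max(np.abs(arr)) > SENSOR_RANGE_G:
                raise ConfigError(
                    f"axis {axis} exceeds the +/-{SENSOR_RANGE_G:g} g sensor range"
                )

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def duration(self) -> float:
        """Time span covered by the samples, s."""
        return (self.n_samples - 1) / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def index_of(self, t: float) -> int:
        """Nearest sample index for time ``t`` (round half up)."""
        return int(np.floor((t - self.t0) * self.fs + 0.5))


@dataclass(frozen=True)
class SignalSeries:
    """A derived scalar signal (total acceleration, jerk, ...) with provenance."""

    values: np.ndarray
    fs: float
    origin_index: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        if arr.ndim != 1 or len(arr) < 1:
            raise ConfigError("signal series must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(arr)):
            raise ConfigError("signal series contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)


def read_recording(
    path, dialect: str = "plain_csv", subject_id: str | None = None
) -> AccelerometerRecording:
    """Read a ``time,x,y,z`` CSV into an :class:`AccelerometerRecording`.

    ``dialect='gcdc_csv'`` additionally tolerates leading metadata lines
    prefixed with ``';'`` as written by GCDC-style loggers. The sampling rate
    is inferred from the median inter-sample interval and the recording is
    rejected if timing jitter exceeds 1% of that interval.
    """
    if dialect not in ("plain_csv", "gcdc_csv"):
        raise ConfigError(f"unknown dialect {dialect!r}")
    times: list[float] = []
    cols: tuple[list[float], list[float], list[float]] = ([], [], [])
    line_nos: list[int] = []
    header_seen = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(";"):
                if dialect == "gcdc_csv":
                    continue
                raise ParseError(f"{path}: line {lineno}: unexpected ';' metadata line")
            if not header_seen:
                header = [c.strip().lower() for c in line.split(",")]
                if header != ["time", "x", "y", "z"]:
                    raise ParseError(
                        f"{path}: line {lineno}: expected header time,x,y,z, got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 fields, got {len(parts)}")
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: malformed numeric value") from None
            times.append(vals[0])
            for c, v in zip(cols, vals[1:]):
                c.append(v)
            line_nos.append(lineno)
    if not header_seen:
        raise ParseError(f"{path}: empty file")
    if len(times) < 2:
        raise ParseError(f"{path}: need at least 2 samples, got {len(times)}")
    t = np.asarray(times)
    dt = np.diff(t)
    bad = np.where(dt <= 0)[0]
    if bad.size:
        raise ParseError(
            f"{path}: line {line_nos[bad[0] + 1]}: non-monotone timestamp"
        )
    med = float(np.median(dt))
    jitter = np.abs(dt - med) / med
    bad = np.where(jitter > JITTER_TOL)[0]
    if bad.size:
        raise ParseError(
            f"{path}: line {line_nos[bad[0] + 1]}: timing jitter exceeds "
            f"{JITTER_TOL:.0%} of the median interval (non-uniform sampling)"
        )
    for name, c in zip("xyz", cols):
        arr = np.asarray(c)
        over = np.where(np.abs(arr) > SENSOR_RANGE_G)[0]
        if over.size:
            raise ParseError(
                f"{path}: line {line_nos[over[0]]}: axis {name} value outside "
                f"+/-{SENSOR_RANGE_G:g} g"
            )
    fs = 1.0 / med
    # snap to an integer rate when the inferred value is within float-printing noise
    if abs(fs - round(fs)) < 1e-6 * max(1.0, round(fs)):
        fs = float(round(fs))
    if subject_id is None:
        import os

        subject_id = os.path.splitext(os.path.basename(str(path)))[0]
    return AccelerometerRecording(
        subject_id=subject_id, fs=fs, x=cols[0], y=cols[1], z=cols[2], t0=float(t[0])
    )


def write_recording(rec: AccelerometerRecording, path) -> None:
    """Write a plain ``time,x,y,z`` CSV at 9 significant digits.

    The format is stable under a write-read-write round trip (byte identical).
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time,x,y,z\n")
        for i in range(rec.n_samples):
            t = rec.t0 + i / rec.fs
            fh.write(f"{t:.9g},{rec.x[i]:.9g},{rec.y[i]:.9g},{rec.z[i]:.9g}\n")


def lowpass_filter(
    rec: AccelerometerRecording, order: int = 8, cutoff: float = 10.0
) -> AccelerometerRecording:
    """Zero-phase low-pass Butterworth conditioning of all three axes.

    An ``order``-th order Butterworth low-pass is designed at ``cutoff`` Hz and
    applied forward-backward (zero phase), so events keep their alignment with
    externally annotated timestamps. The effective magnitude response is the
    *square* of the designed single-pass response; the phase response is zero.
    """
    if cutoff >= rec.fs / 2:
        raise ConfigError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency {rec.fs / 2} Hz"
        )
    min_len = 3 * (order + 1) + 1
    if rec.n_samples < min_len:
        raise DegenerateSignalError(
            f"recording too short to filter ({rec.n_samples} samples, need {min_len})"
        )
    sos = _sps.butter(order, cutoff, btype="low", fs=rec.fs, output="sos")
    out = {a: _sps.sosfiltfilt(sos, getattr(rec, a)) for a in ("x", "y", "z")}
    return replace(rec, **out)


def total_acceleration(rec_or_axes) -> SignalSeries:
    """Euclidean norm of the three axes at each sample, in g."""
    if isinstance(rec_or_axes, AccelerometerRecording):
        x, y, z = rec_or_axes.x, rec_or_axes.y, rec_or_axes.z
        fs = rec_or_axes.fs
    else:
        x, y, z, fs = rec_or_axes
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    return SignalSeries(values=np.sqrt(x * x + y * y + z * z), fs=fs)


def jerk(series: SignalSeries) -> SignalSeries:
    """Forward first difference scaled by fs: out[i] = (v[i+1]-v[i])*fs, g/s.

    Length is n-1; the forward difference keeps the minimum-jerk location
    causally tied to the onset of the underlying movement.
    """
    if len(series) < 2:
        raise DegenerateSignalError("insufficient samples for jerk (need >= 2)")
    return SignalSeries(
        values=np.diff(series.values) * series.fs,
        fs=series.fs,
        origin_index=series.origin_index,
    )
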