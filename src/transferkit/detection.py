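"""The 59-feature vector per 25-sample window for transfer-occurrence detection.

Fourteen features are computed for each of the four signals X, Y, Z and the
total acceleration vector — SD, variance, five percentiles, interquartile
range, 10th-90th percentile range, lag-one autocorrelation over a 10 s
context, three Daubechies-2 two-level wavelet coefficient norms, and sample
entropy — plus the three pairwise axis cross-correlations: 14 x 4 + 3 = 59.

The composition (sample entropy on all four signals, including the total
vector) is the only one consistent with the 59-feature total; it is isolated
behind :func:`feature_names` so an alternate composition can be configured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError, DegenerateSignalError
from .featurematrix import FeatureMatrix
from .segmentation import DetectionWindow
from .signal import AccelerometerRecording

PER_SIGNAL_FEATURES = (
    "sd",
    "variance",
    "p10",
    "p25",
    "p50",
    "p75",
    "p90",
    "iqr",
    "range_p10_p90",
    "lag1_corr",
    "wnorm_d1",
    "wnorm_d2",
    "wnorm_a2",
    "sampen",
)
SIGNAL_ORDER = ("x", "y", "z", "total")
CROSS_FEATURES = ("cross_corr_xy", "cross_corr_xz", "cross_corr_yz")

CONTEXT_SECONDS = 10.0
SAMPEN_M = 2
SAMPEN_R_FRAC = 0.3
WAVELET = "db2"
WAVELET_LEVEL = 2
WAVELET_MODE = "symmetric"


def feature_names() -> list[str]:
    """The canonical ordered list of the 59 detection feature names."""
    names = [f"{sig}_{feat}" for sig in SIGNAL_ORDER for feat in PER_SIGNAL_FEATURES]
    names.extend(CROSS_FEATURES)
    return names


@dataclass(frozen=True)
class DetectionFeatureVector:
    window_ref: tuple[str, int]
    features: Mapping[str, float]
    label: str | None = None


def basic_stats(values) -> dict[str, float]:
    """SD (n-1 denominator), variance = sd^2, linear-interpolation percentiles,
    IQR and the 10th-90th percentile range."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise DegenerateSignalError("basic stats require >= 2 samples")
    sd = float(np.std(v, ddof=1))
    p10, p25, p50, p75, p90 = (float(p) for p in np.percentile(v, [10, 25, 50, 75, 90]))
    return {
        "sd": sd,
        "variance": sd * sd,
        "p10": p10,
        "p25": p25,
        "p50": p50,
        "p75": p75,
        "p90": p90,
        "iqr": p75 - p25,
        "range_p10_p90": p90 - p10,
    }


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a0 = a - a.mean()
    b0 = b - b.mean()
    den = np.sqrt(np.sum(a0 * a0) * np.sum(b0 * b0))
    if den == 0.0:
        return 0.0  # correlation undefined for a zero-variance input
    return float(np.sum(a0 * b0) / den)


def lag_one_correlation(context) -> float:
    """Pearson correlation of the context with its one-sample shift.

    The context is the 10 s of signal centered on the analysis window,
    truncated at recording edges; this captures temporal dynamics around the
    window rather than within it.
    """
    c = np.asarray(context, dtype=float)
    if len(c) < 3:
        raise DegenerateSignalError("lag-one correlation requires >= 3 samples")
    return _pearson(c[:-1], c[1:])


def wavelet_norms(values, mode: str = WAVELET_MODE) -> tuple[float, float, float]:
    """Euclidean norms of the db2 level-1 detail, level-2 detail and level-2
    approximation coefficients of a two-level decomposition."""
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise DegenerateSignalError("too short for 2-level decomposition")
    ca2, cd2, cd1 = pywt.wavedec(v, WAVELET, mode=mode, level=WAVELET_LEVEL)
    return (
        float(np.linalg.norm(cd1)),
        float(np.linalg.norm(cd2)),
        float(np.linalg.norm(ca2)),
    )


def sample_entropy(values, m: int = SAMPEN_M, r_frac: float = SAMPEN_R_FRAC) -> float:
    """Sample entropy -ln(A/B) with Chebyshev distance and self-matches excluded.

    Tolerance is ``r_frac`` times the (n-1 denominator) SD of the series. A
    constant series is defined as maximally regular (0). When either template
    count is zero the finite sentinel ``ln((n-m)(n-m-1))`` is returned so
    downstream classifiers never see infinities.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < m + 2:
        raise DegenerateSignalError(f"sample entropy requires >= {m + 2} samples")
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        return 0.0
    r = r_frac * sd
    emb = sliding_window_view(v, m + 1)  # (n-m, m+1)
    diff = np.abs(emb[:, None, :] - emb[None, :, :])
    d_m = diff[:, :, :m].max(axis=2)
    d_m1 = diff.max(axis=2)
    iu = np.triu_indices(len(emb), k=1)
    b = int(np.count_nonzero(d_m[iu] <= r))
    a = int(np.count_nonzero(d_m1[iu] <= r))
    if a == 0 or b == 0:
        return float(np.log((n - m) * (n - m - 1)))
    return float(-np.log(a / b))


def cross_correlation(a, b) -> float:
    """Lag-zero Pearson correlation between two equal-length windows."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ConfigError("cross-correlation inputs must have equal length")
    return _pearson(a, b)


def _context_bounds(center: int, n: int, fs: float) -> tuple[int, int]:
    half = int(round(CONTEXT_SECONDS * fs / 2))
    return max(0, center - half), min(n, center + half)


def window_features(
    window: DetectionWindow, rec: AccelerometerRecording
) -> DetectionFeatureVector:
    """Assemble the 59 features for one window (scalar reference path)."""
    try:
        sigs = {
            "x": window.x,
            "y": window.y,
            "z": window.z,
            "total": np.sqrt(window.x**2 + window.y**2 + window.z**2),
        }
        center = window.start_index + window.width // 2
        lo, hi = _context_bounds(center, rec.n_samples, rec.fs)
        ctx = {
            "x": rec.x[lo:hi],
            "y": rec.y[lo:hi],
            "z": rec.z[lo:hi],
        }
        ctx["total"] = np.sqrt(ctx["x"] ** 2 + ctx["y"] ** 2 + ctx["z"] ** 2)
        feats: dict[str, float] = {}
        for sig in SIGNAL_ORDER:
            v = sigs[sig]
            stats = basic_stats(v)
            d1, d2, a2 = wavelet_norms(v)
            per = {
                **stats,
                "lag1_corr": lag_one_correlation(ctx[sig]),
                "wnorm_d1": d1,
                "wnorm_d2": d2,
                "wnorm_a2": a2,
                "sampen": sample_entropy(v),
            }
            for feat in PER_SIGNAL_FEATURES:
                feats[f"{sig}_{feat}"] = per[feat]
        feats["cross_corr_xy"] = cross_correlation(window.x, window.y)
        feats["cross_corr_xz"] = cross_correlation(window.x, window.z)
        feats["cross_corr_yz"] = cross_correlation(window.y, window.z)
    except Exception as exc:
        raise type(exc)(
            f"window at start {window.start_index}: {exc}"
        ) from exc
    return DetectionFeatureVector(
        window_ref=(rec.subject_id, window.start_index),
        features=feats,
        label=window.label,
    )


# ---------------------------------------------------------------------------
# Vectorized batch extraction (used by the pipelines; equals the scalar path)
# ---------------------------------------------------------------------------


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A0 = A - A.mean(axis=1, keepdims=True)
    B0 = B - B.mean(axis=1, keepdims=True)
    num = np.sum(A0 * B0, axis=1)
    den = np.sqrt(np.sum(A0 * A0, axis=1) * np.sum(B0 * B0, axis=1))
    out = np.zeros(len(A))
    np.divide(num, den, out=out, where=den > 0)
    return out


def _batch_sampen(W: np.ndarray, m: int = SAMPEN_M, r_frac: float = SAMPEN_R_FRAC) -> np.ndarray:
    nwin, n = W.shape
    sd = np.std(W, axis=1, ddof=1)
    out = np.zeros(nwin)
    nonconst = sd > 0
    idx = np.where(nonconst)[0]
    iu = np.triu_indices(n - m, k=1)
    cap = np.log((n - m) * (n - m - 1))
    for chunk in np.array_split(idx, max(1, len(idx) // 512)):
        if len(chunk) == 0:
            continue
        emb = sliding_window_view(W[chunk], m + 1, axis=1)  # (c, n-m, m+1)
        diff = np.abs(emb[:, :, None, :] - emb[:, None, :, :])  # (c, n-m, n-m, m+1)
        d_m = diff[..., :m].max(axis=-1)[:, iu[0], iu[1]]
        d_m1 = diff.max(axis=-1)[:, iu[0], iu[1]]
        r = (r_frac * sd[chunk])[:, None]
        b = np.count_nonzero(d_m <= r, axis=1)
        a = np.count_nonzero(d_m1 <= r, axis=1)
        vals = np.where((a > 0) & (b > 0), -np.log(np.maximum(a, 1) / np.maximum(b, 1)), cap)
        out[chunk] = vals
    return out


def extract_detection_features(
    rec: AccelerometerRecording, windows: Sequence[DetectionWindow]
) -> FeatureMatrix:
    """Compute the 59-feature matrix for a sequence of labeled windows.

    Vectorized across windows; numerically equal to looping
    :func:`window_features` (asserted in the test suite).
    """
    if not windows:
        raise ConfigError("no windows to featurize")
    starts = np.asarray([w.start_index for w in windows])
    width = windows[0].width
    axes = {
        "x": np.stack([w.x for w in windows]),
        "y": np.stack([w.y for w in windows]),
        "z": np.stack([w.z for w in windows]),
    }
    axes["total"] = np.sqrt(axes["x"] ** 2 + axes["y"] ** 2 + axes["z"] ** 2)
    rec_total = np.sqrt(rec.x**2 + rec.y**2 + rec.z**2)
    rec_sigs = {"x": rec.x, "y": rec.y, "z": rec.z, "total": rec_total}

    cols: dict[str, np.ndarray] = {}
    centers = starts + width // 2
    for sig in SIGNAL_ORDER:
        W = axes[sig]
        sd = np.std(W, axis=1, ddof=1)
        pct = np.percentile(W, [10, 25, 50, 75, 90], axis=1)
        coeffs = pywt.wavedec(W, WAVELET, mode=WAVELET_MODE, level=WAVELET_LEVEL, axis=1)
        ca2, cd2, cd1 = coeffs
        lag1 = np.empty(len(windows))
        for i, c in enumerate(centers):
            lo, hi = _context_bounds(int(c), rec.n_samples, rec.fs)
            ctx = rec_sigs[sig][lo:hi]
            lag1[i] = _pearson(ctx[:-1], ctx[1:])
        cols[f"{sig}_sd"] = sd
        cols[f"{sig}_variance"] = sd * sd
        for q, row in zip(("p10", "p25", "p50", "p75", "p90"), pct):
            cols[f"{sig}_{q}"] = row
        cols[f"{sig}_iqr"] = pct[3] - pct[1]
        cols[f"{sig}_range_p10_p90"] = pct[4] - pct[0]
        cols[f"{sig}_lag1_corr"] = lag1
        cols[f"{sig}_wnorm_d1"] = np.linalg.norm(cd1, axis=1)
        cols[f"{sig}_wnorm_d2"] = np.linalg.norm(cd2, axis=1)
        cols[f"{sig}_wnorm_a2"] = np.linalg.norm(ca2, axis=1)
        cols[f"{sig}_sampen"] = _batch_sampen(W)
    cols["cross_corr_xy"] = _rowwise_pearson(axes["x"], axes["y"])
    cols["cross_corr_xz"] = _rowwise_pearson(axes["x"], axes["z"])
    cols["cross_corr_yz"] = _rowwise_pearson(axes["y"], axes["z"])

    names = feature_names()
    X = np.column_stack([cols[n] for n in names])
    labels = np.asarray(
        [w.label if w.label is not None else "unlabeled" for w in windows], dtype=object
    )
    groups = np.asarray([rec.subject_id] * len(windows), dtype=object)
    row_ids = [f"{rec.subject_id}:{s}" for s in starts]
    return FeatureMatrix(
        feature_names=names, X=X, labels=labels, groups=groups, row_ids=row_ids
    )
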