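"""The 59-feature detection vector and its component statistics."""

import numpy as np
import pytest
import pywt

from transferkit.detection import (
    CROSS_FEATURES,
    PER_SIGNAL_FEATURES,
    basic_stats,
    cross_correlation,
    extract_detection_features,
    feature_names,
    lag_one_correlation,
    sample_entropy,
    wavelet_norms,
    window_features,
)
from transferkit.errors import DegenerateSignalError
from transferkit.segmentation import DetectionWindow, label_windows, slide_windows
from transferkit.signal import AccelerometerRecording


class TestFeatureCatalog:
    def test_exactly_59_names_in_canonical_order(self):
        names = feature_names()
        assert len(names) == 59
        assert names[0] == "x_sd"
        assert names[13] == "x_sampen"
        assert names[14] == "y_sd"
        assert names[-3:] == list(CROSS_FEATURES)
        assert len(PER_SIGNAL_FEATURES) == 14


class TestBasicStats:
    def test_linear_interpolation_percentiles_on_1_to_25(self):
        s = basic_stats(np.arange(1.0, 26.0))
        assert s["p50"] == pytest.approx(13.0)
        assert s["iqr"] == pytest.approx(12.0)
        assert s["range_p10_p90"] == pytest.approx(19.2)
        assert s["p10"] == pytest.approx(3.4)
        assert s["p90"] == pytest.approx(22.6)

    def test_constant_series(self):
        s = basic_stats(np.full(25, 2.5))
        assert s["sd"] == s["variance"] == s["iqr"] == s["range_p10_p90"] == 0.0
        assert s["p10"] == s["p50"] == s["p90"] == 2.5

    def test_variance_is_sd_squared(self, rng):
        s = basic_stats(rng.normal(size=25))
        assert s["variance"] == pytest.approx(s["sd"] ** 2, abs=1e-12)

    def test_percentile_monotonicity(self, rng):
        for _ in range(20):
            s = basic_stats(rng.normal(size=25))
            assert s["p10"] <= s["p25"] <= s["p50"] <= s["p75"] <= s["p90"]


class TestLagOneCorrelation:
    def test_alternating_sequence_is_minus_one(self):
        c = np.tile([1.0, -1.0], 13)
        assert lag_one_correlation(c) == pytest.approx(-1.0)

    def test_linear_ramp_is_nearly_one(self):
        assert lag_one_correlation(np.arange(250.0)) > 0.99

    def test_matches_direct_pearson(self, rng):
        c = rng.normal(size=250)
        a, b = c[:-1], c[1:]
        expected = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert lag_one_correlation(c) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_returns_zero(self):
        assert lag_one_correlation(np.ones(10)) == 0.0


def _dwt_oracle(x, mode="symmetric"):
    """Independent convolve-and-decimate db2 single-level decomposition."""
    w = pywt.Wavelet("db2")
    k = w.dec_len - 1
    x = np.asarray(x, dtype=float)
    if mode == "symmetric":
        ext = np.concatenate([x[:k][::-1], x, x[-k:][::-1]])
        lo = np.convolve(ext, w.dec_lo, mode="valid")[1::2]
        hi = np.convolve(ext, w.dec_hi, mode="valid")[1::2]
    elif mode == "periodization":
        # even length via wrap, then circular convolution
        if len(x) % 2:
            x = np.concatenate([x, x[-1:]])
        ext = np.concatenate([x[-k:], x, x[:k]])
        lo = np.convolve(ext, w.dec_lo, mode="valid")[1::2][: len(x) // 2]
        hi = np.convolve(ext, w.dec_hi, mode="valid")[1::2][: len(x) // 2]
    else:
        raise ValueError(mode)
    return lo, hi


def _wavelet_norms_oracle(x, mode="symmetric"):
    ca1, cd1 = _dwt_oracle(x, mode)
    ca2, cd2 = _dwt_oracle(ca1, mode)
    return (
        float(np.linalg.norm(cd1)),
        float(np.linalg.norm(cd2)),
        float(np.linalg.norm(ca2)),
    )


class TestWaveletNorms:
    def test_zero_series(self):
        assert wavelet_norms(np.zeros(25)) == (0.0, 0.0, 0.0)

    def test_constant_series_annihilated_by_details(self):
        d1, d2, a2 = wavelet_norms(np.full(25, 3.0))
        assert d1 == pytest.approx(0.0, abs=1e-10)
        assert d2 == pytest.approx(0.0, abs=1e-10)
        assert a2 > 0

    def test_matches_convolve_and_decimate_oracle(self, rng):
        for _ in range(10):
            v = rng.normal(size=25)
            got = wavelet_norms(v)
            expected = _wavelet_norms_oracle(v)
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_periodization_conserves_energy(self, rng):
        # db2 is orthogonal: with periodization the coefficient energy equals
        # the signal energy (not true for symmetric padding, which inflates
        # the coefficient count)
        v = rng.normal(size=24)
        d1, d2, a2 = wavelet_norms(v, mode="periodization")
        assert d1**2 + d2**2 + a2**2 == pytest.approx(np.sum(v * v), abs=1e-9)

    def test_too_short(self):
        with pytest.raises(DegenerateSignalError):
            wavelet_norms(np.ones(3))


def _sampen_brute(v, m=2, r_frac=0.3):
    v = np.asarray(v, dtype=float)
    n = len(v)
    sd = np.std(v, ddof=1)
    if sd == 0:
        return 0.0
    r = r_frac * sd
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(v[i + k] - v[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(v[i + m] - v[j + m]) <= r:
                    a += 1
    if a == 0 or b == 0:
        return float(np.log((n - m) * (n - m - 1)))
    return float(-np.log(a / b))


class TestSampleEntropy:
    def test_periodic_alternation_is_zero(self):
        v = np.array([0.0, 1.0] * 12 + [0.0])
        assert sample_entropy(v) == pytest.approx(0.0)

    def test_constant_series_is_zero(self):
        assert sample_entropy(np.full(25, 0.7)) == 0.0

    def test_matches_brute_force_loop(self, rng):
        for _ in range(10):
            v = rng.normal(size=25)
            assert sample_entropy(v) == pytest.approx(_sampen_brute(v), abs=1e-12)

    def test_no_match_sentinel_is_finite(self):
        # all length-2 templates are farther apart than the tolerance, so
        # B = 0 and the documented cap ln((n-m)(n-m-1)) is returned
        v = np.array([0.0, 10.0, 0.0, -10.0, 0.0])
        got = sample_entropy(v)
        assert got == pytest.approx(np.log((5 - 2) * (5 - 2 - 1)), abs=1e-12)
        assert got == pytest.approx(_sampen_brute(v), abs=1e-12)

    def test_too_short(self):
        with pytest.raises(DegenerateSignalError):
            sample_entropy(np.ones(3))


class TestCrossCorrelation:
    def test_identical_and_inverted(self, rng):
        v = rng.normal(size=25)
        assert cross_correlation(v, v) == pytest.approx(1.0)
        assert cross_correlation(v, -v) == pytest.approx(-1.0)

    def test_matches_formula_and_symmetry(self, rng):
        a, b = rng.normal(size=(2, 25))
        expected = np.corrcoef(a, b)[0, 1]
        assert cross_correlation(a, b) == pytest.approx(expected, abs=1e-12)
        assert cross_correlation(a, b) == cross_correlation(b, a)

    def test_zero_variance_returns_zero(self, rng):
        assert cross_correlation(np.ones(25), rng.normal(size=25)) == 0.0


def _rec_from(x, y, z, fs=25.0):
    return AccelerometerRecording("r", fs, x, y, z)


class TestWindowFeatures:
    def test_59_features_in_canonical_order(self, rng):
        n = 500
        rec = _rec_from(*(0.2 * rng.normal(size=(3, n)) + [[1.0], [0.0], [0.0]]))
        w = slide_windows(rec)[3]
        vec = window_features(w, rec)
        assert list(vec.features.keys()) == feature_names()
        assert len(vec.features) == 59
        assert all(np.isfinite(v) for v in vec.features.values())

    def test_all_zero_recording_gives_all_zero_features(self):
        n = 300
        rec = _rec_from(np.zeros(n), np.zeros(n), np.zeros(n))
        vec = window_features(slide_windows(rec)[2], rec)
        assert set(vec.features.values()) == {0.0}

    def test_only_lag1_changes_under_time_shift(self, rng):
        # same 25 samples placed at two positions inside different contexts
        content = 0.3 * rng.normal(size=(3, 25))
        base = 0.05 * rng.normal(size=(3, 600))
        sig = base.copy()
        sig[:, 100:125] = content
        sig[:, 400:425] = content
        rec = _rec_from(sig[0] + 1.0, sig[1], sig[2])
        w1 = DetectionWindow(100, 25, rec.x[100:125], rec.y[100:125], rec.z[100:125])
        w2 = DetectionWindow(400, 25, rec.x[400:425], rec.y[400:425], rec.z[400:425])
        f1 = window_features(w1, rec).features
        f2 = window_features(w2, rec).features
        for name in feature_names():
            if name.endswith("lag1_corr"):
                continue
            assert f1[name] == pytest.approx(f2[name], abs=1e-12), name

    def test_scale_equivariance(self, rng):
        n = 400
        x, y, z = 0.2 * rng.normal(size=(3, n))
        k = 3.0
        rec1 = _rec_from(x, y, z)
        rec2 = _rec_from(k * x, k * y, k * z)
        w1 = slide_windows(rec1)[5]
        w2 = slide_windows(rec2)[5]
        f1 = window_features(w1, rec1).features
        f2 = window_features(w2, rec2).features
        scaled = ("sd", "variance", "iqr", "range_p10_p90", "wnorm_d1", "wnorm_d2",
                  "wnorm_a2", "p10", "p25", "p50", "p75", "p90")
        for name in feature_names():
            stem = name.split("_", 1)[1] if not name.startswith("cross") else name
            if stem == "variance":
                assert f2[name] == pytest.approx(k * k * f1[name], rel=1e-9), name
            elif stem in scaled:
                assert f2[name] == pytest.approx(k * f1[name], rel=1e-9), name
            else:  # lag1_corr, sampen, cross-correlations are scale-free
                assert f2[name] == pytest.approx(f1[name], abs=1e-9), name

    def test_batch_extraction_equals_scalar_path(self, small_dataset):
        rec = small_dataset.recordings[0]
        anns = small_dataset.annotations_for(rec.subject_id)
        windows = label_windows(slide_windows(rec), anns, rec.fs, rec.t0)[:40]
        fm = extract_detection_features(rec, windows)
        for i in (0, 7, 23, 39):
            vec = window_features(windows[i], rec)
            np.testing.assert_allclose(
                fm.X[i], [vec.features[n] for n in fm.feature_names], atol=1e-10
            )
            assert fm.labels[i] == vec.label

    def test_determinism(self, rng):
        n = 300
        rec = _rec_from(*(0.1 * rng.normal(size=(3, n))))
        w = slide_windows(rec)[1]
        f1 = window_features(w, rec).features
        f2 = window_features(w, rec).features
        assert list(f1.items()) == list(f2.items())
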