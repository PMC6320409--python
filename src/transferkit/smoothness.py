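"""Movement-smoothness metrics: spectral arc length and dimensionless jerk.

Both metrics are negative numbers where values closer to zero indicate a
smoother movement profile. SPARC measures the arc length of the normalized
magnitude spectrum of the profile; dimensionless jerk integrates the squared
second derivative of a velocity profile, normalized by duration and peak
speed so it is invariant to movement amplitude and comparable across windows.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateSignalError


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1).bit_length())


def sparc(
    values,
    fs: float,
    fc_max: float = 10.0,
    amp_threshold: float = 0.05,
    pad_factor: int = 4,
) -> float:
    """Spectral arc length of a movement profile.

    The magnitude spectrum is computed with a zero-padded DFT (pad to
    ``pad_factor`` times the next power of two), normalized by its 0 Hz
    magnitude, and truncated at the smaller of ``fc_max`` and the highest
    frequency whose normalized magnitude still reaches ``amp_threshold``
    (adaptive cutoff). The returned value is minus the arc length of the
    normalized spectrum over that band, with frequency rescaled to [0, 1].
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 4:
        raise DegenerateSignalError("sparc requires a 1-d series of length >= 4")
    nfft = pad_factor * _next_pow2(len(v))
    mag = np.abs(np.fft.rfft(v, nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    if mag[0] == 0.0:
        raise DegenerateSignalError("degenerate spectrum: zero magnitude at 0 Hz")
    mag_n = mag / mag[0]
    in_cap = freqs <= fc_max
    above = np.where(in_cap & (mag_n >= amp_threshold))[0]
    i_cut = above[-1]  # index 0 always qualifies (mag_n[0] == 1)
    f_band = freqs[: i_cut + 1]
    m_band = mag_n[: i_cut + 1]
    if f_band[-1] == 0.0:
        return 0.0  # single-point band: zero arc
    f_hat = f_band / f_band[-1]
    arc = float(np.sum(np.sqrt(np.diff(f_hat) ** 2 + np.diff(m_band) ** 2)))
    return -arc


def dimensionless_jerk(values, fs: float) -> tuple[float, float]:
    """Dimensionless jerk and its negative-log variant for a velocity profile.

    ``dj = -(T^3 / v_peak^2) * sum(a''^2) / fs`` where ``T`` is the window
    duration, ``v_peak`` the peak absolute velocity and ``a''`` the second
    difference of the velocity scaled to physical units (rectangle-rule
    integral at 1/fs). ``ldj = -ln|dj|``. Scaling the velocity by any k != 0
    leaves both unchanged.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise DegenerateSignalError("dimensionless jerk requires length >= 3")
    v_peak = float(np.max(np.abs(v)))
    if v_peak == 0.0:
        raise DegenerateSignalError("zero peak velocity")
    T = (len(v) - 1) / fs
    j = np.diff(v, n=2) * fs**2
    integral = float(np.sum(j * j)) / fs
    dj = -(T**3 / v_peak**2) * integral
    with np.errstate(divide="ignore"):
        ldj = -float(np.log(np.abs(dj))) if dj != 0.0 else float("inf")
    return dj, ldj
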