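"""Per-window feature extraction: the 54-feature vector.

Each 1-s window of triaxial acceleration yields 54 features:

* 30 time-domain: per axis (x, y, z) the mean, sample standard deviation,
  coefficient of variation, skewness, excess kurtosis, minimum, 25th
  percentile, median, 75th percentile and maximum;
* 2 magnitude: mean and standard deviation of the resultant
  r_i = sqrt(ax_i^2 + ay_i^2 + az_i^2);
* 16 spectral: per series (x, y, z, r) the dominant frequency, dominant
  magnitude, total power and median frequency of the mean-removed FFT
  spectrum (DC excluded);
* 3 cross-axis Pearson correlations (xy, xz, yz);
* 3 orientation angles (roll, pitch, yaw) from the gravity component
  estimated with a 2nd-order, 1 Hz low-pass Butterworth filter applied
  forward-backward (zero net phase).

Conventions pinned here (they matter when comparing against other code):

* sd uses the n-1 denominator; skewness and kurtosis use central moments
  with n denominators; kurtosis is excess (normal -> 0); a constant series
  has skew = kurt = 0 by convention.
* cv = sd / max(|mean|, 1e-6): the guard keeps the feature bounded on
  zero-mean horizontal axes.
* Percentiles use linear interpolation between order statistics.
* Spectral features are computed on the mean-removed series over bins
  k = 1..floor(N/2) (DC excluded, so gravity does not dominate every
  window); argmax ties resolve to the lowest frequency; dominant magnitude
  is normalized by N; total power is sum(M_k^2) / N^2; median frequency is
  the lowest bin where cumulative squared magnitude reaches half the total.
* A zero-variance axis gives correlation 0 by convention.
* Yaw (rotation about gravity) is not observable from a static
  accelerometer; the reported angle, atan2(gx, gy), is a documented
  convention, not a physical heading.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .io import METADATA_COLUMNS, LabeledWindow

#: Guard on |mean| in the coefficient-of-variation denominator, in g.
CV_EPSILON: float = 1e-6

#: Low-pass cutoff (Hz) and order of the orientation (gravity) filter.
ORIENTATION_CUTOFF_HZ: float = 1.0
ORIENTATION_FILTER_ORDER: int = 2

#: Forward-backward filtering pads the window with a reflected ("even")
#: extension of this many samples at each end before filtering.
ORIENTATION_PAD_SAMPLES: int = 9

_TIME_STATS = ("mean", "sd", "cv", "skew", "kurt", "min", "p25", "median", "p75", "max")
_SPECTRAL_STATS = ("domfreq", "dommag", "totpower", "medfreq")

#: The fixed, documented order of the 54 feature columns. The composition
#: (time stats per axis, resultant magnitude stats, spectral stats per axis
#: and per resultant, pairwise correlations, orientation angles) lives only
#: here, so alternate compositions are a one-line edit.
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"{stat}_{axis}" for axis in "xyz" for stat in _TIME_STATS)
    + ("mean_r", "sd_r")
    + tuple(f"{stat}_{series}" for series in ("x", "y", "z", "r") for stat in _SPECTRAL_STATS)
    + ("corr_xy", "corr_xz", "corr_yz")
    + ("roll", "pitch", "yaw")
)

N_FEATURES: int = len(FEATURE_NAMES)


def _check_series(series: np.ndarray, min_length: int, name: str) -> np.ndarray:
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError(f"{name} expects a 1-D series")
    if series.size < min_length:
        raise ValueError(f"{name} requires at least {min_length} samples, got {series.size}")
    if not np.all(np.isfinite(series)):
        raise ValueError(f"{name}: series contains non-finite values")
    return series


def time_features(series: Sequence[float]) -> tuple[float, ...]:
    """Ten time-domain statistics of one axis.

    Returns ``(mean, sd, cv, skew, kurt, min, p25, median, p75, max)``.
    """
    x = _check_series(np.asarray(series), 2, "time_features")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    cv = sd / max(abs(mean), CV_EPSILON)
    centered = x - mean
    m2 = float(np.mean(centered**2))
    if m2 == 0.0:
        skew = 0.0
        kurt = 0.0
    else:
        m3 = float(np.mean(centered**3))
        m4 = float(np.mean(centered**4))
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0
    p0, p25, p50, p75, p100 = np.percentile(x, [0, 25, 50, 75, 100], method="linear")
    return (mean, sd, cv, skew, kurt, float(p0), float(p25), float(p50), float(p75), float(p100))


def magnitude_features(window: LabeledWindow | np.ndarray) -> tuple[float, float]:
    """Mean and (n-1) standard deviation of the per-sample resultant magnitude."""
    samples = window.window_samples if isinstance(window, LabeledWindow) else np.asarray(window)
    r = np.sqrt(np.sum(np.asarray(samples, dtype=float) ** 2, axis=1))
    if r.size < 2:
        raise ValueError("magnitude_features requires at least 2 samples")
    return float(np.mean(r)), float(np.std(r, ddof=1))


def frequency_features(series: Sequence[float], fs: float) -> tuple[float, float, float, float]:
    """Spectral features of one series: (domfreq, dommag, totpower, medfreq).

    The series is mean-removed before the FFT and only bins
    k = 1..floor(N/2) are considered, so the gravity offset never registers
    as the dominant frequency. For an all-zero spectrum (constant input)
    the dominant and median frequencies fall back to the lowest bin and
    the magnitudes are 0.
    """
    x = _check_series(np.asarray(series), 4, "frequency_features")
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = x.size
    spectrum = np.fft.rfft(x - np.mean(x))
    mags = np.abs(spectrum[1:])  # bins 1..floor(N/2); DC excluded
    freqs = np.arange(1, mags.size + 1) * fs / n
    power = mags**2 / n**2
    totpower = float(np.sum(power))
    if totpower == 0.0:
        return float(freqs[0]), 0.0, 0.0, float(freqs[0])
    dom = int(np.argmax(mags))  # first maximum -> lowest frequency on ties
    cumulative = np.cumsum(power)
    med = int(np.searchsorted(cumulative, 0.5 * totpower))
    return float(freqs[dom]), float(mags[dom] / n), totpower, float(freqs[med])


def cross_axis_correlations(
    window: LabeledWindow | np.ndarray,
) -> tuple[float, float, float]:
    """Pearson correlations (xy, xz, yz); a zero-variance axis gives 0."""
    samples = window.window_samples if isinstance(window, LabeledWindow) else np.asarray(window)
    samples = np.asarray(samples, dtype=float)
    if samples.shape[0] < 2:
        raise ValueError("cross_axis_correlations requires at least 2 samples")
    sds = np.std(samples, axis=0)
    out = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        if sds[i] == 0.0 or sds[j] == 0.0:
            out.append(0.0)
        else:
            out.append(float(np.corrcoef(samples[:, i], samples[:, j])[0, 1]))
    return tuple(out)  # type: ignore[return-value]


def orientation_features(
    window: LabeledWindow | np.ndarray, fs: float
) -> tuple[float, float, float]:
    """Roll, pitch, yaw (radians) from the low-pass gravity estimate.

    Each axis is filtered with a 2nd-order Butterworth low-pass at 1 Hz,
    applied forward and backward so the net phase shift is zero; the
    filtered window means (gx, gy, gz) estimate the gravity direction, and

        roll  = atan2(gy, gz)
        pitch = atan2(-gx, sqrt(gy^2 + gz^2))
        yaw   = atan2(gx, gy)   (convention only; not identifiable)
    """
    samples = window.window_samples if isinstance(window, LabeledWindow) else np.asarray(window)
    samples = np.asarray(samples, dtype=float)
    if fs <= 2 * ORIENTATION_CUTOFF_HZ:
        raise ValueError("fs must exceed twice the orientation filter cutoff")
    if samples.shape[0] <= ORIENTATION_PAD_SAMPLES:
        raise ValueError(
            f"orientation_features requires more than {ORIENTATION_PAD_SAMPLES} samples "
            f"to pad the zero-phase filter, got {samples.shape[0]}"
        )
    b, a = butter(ORIENTATION_FILTER_ORDER, ORIENTATION_CUTOFF_HZ, btype="low", fs=fs)
    filtered = filtfilt(b, a, samples, axis=0, padtype="even", padlen=ORIENTATION_PAD_SAMPLES)
    gx, gy, gz = filtered.mean(axis=0)
    roll = math.atan2(gy, gz)
    pitch = math.atan2(-gx, math.hypot(gy, gz))
    yaw = math.atan2(gx, gy)
    return roll, pitch, yaw


def extract_window_features(window: LabeledWindow, fs: float) -> dict[str, float]:
    """The full 54-value feature dict for one window, keyed by FEATURE_NAMES."""
    samples = window.window_samples
    values: dict[str, float] = {}
    for axis_index, axis in enumerate("xyz"):
        stats = time_features(samples[:, axis_index])
        for stat_name, value in zip(_TIME_STATS, stats):
            values[f"{stat_name}_{axis}"] = value
    values["mean_r"], values["sd_r"] = magnitude_features(window)
    r = np.sqrt(np.sum(samples**2, axis=1))
    series = {"x": samples[:, 0], "y": samples[:, 1], "z": samples[:, 2], "r": r}
    for name, data in series.items():
        for stat_name, value in zip(_SPECTRAL_STATS, frequency_features(data, fs)):
            values[f"{stat_name}_{name}"] = value
    values["corr_xy"], values["corr_xz"], values["corr_yz"] = cross_axis_correlations(window)
    values["roll"], values["pitch"], values["yaw"] = orientation_features(window, fs)
    return values


def extract_features(windows: Sequence[LabeledWindow], fs: float) -> pd.DataFrame:
    """Feature matrix: one row per window, 54 feature columns plus metadata.

    Column order is ``FEATURE_NAMES`` followed by ``METADATA_COLUMNS``.
    Per-window failures are re-raised with the window's identity attached.
    """
    rows = []
    for window in windows:
        try:
            values = extract_window_features(window, fs)
        except ValueError as exc:
            raise ValueError(
                f"feature extraction failed for window {window.window_index} "
                f"(participant {window.participant_id!r}, label {window.label!r}): {exc}"
            ) from exc
        values["participant_id"] = window.participant_id
        values["placement"] = window.placement
        values["label"] = window.label
        values["window_index"] = window.window_index
        rows.append(values)
    columns = list(FEATURE_NAMES) + list(METADATA_COLUMNS)
    if not rows:
        frame = pd.DataFrame(columns=columns)
        return frame.astype({name: float for name in FEATURE_NAMES} | {"window_index": int})
    return pd.DataFrame(rows, columns=columns)
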