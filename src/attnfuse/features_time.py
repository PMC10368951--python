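"""Twelve time-domain features per channel per epoch.

Order (fixed, used everywhere downstream): standard deviation, mean,
peak-to-peak amplitude, skewness, kurtosis, RMS, Hjorth mobility, quantile,
Hjorth complexity, variance, decorrelation time, number of zero-crossings.

Hjorth descriptors follow the classical variance-ratio definitions with
derivatives taken as first differences:

    activity   = var(x)
    mobility   = sd(dx) / sd(x)
    complexity = (sd(ddx) / sd(dx)) / (sd(dx) / sd(x))
"""

from __future__ import annotations

import numpy as np

TIME_FEATURE_NAMES: tuple[str, ...] = (
    "std", "mean", "ptp", "skewness", "kurtosis", "rms",
    "hjorth_mobility", "quantile75", "hjorth_complexity", "variance",
    "decorrelation_time", "zero_crossings",
)

TIME_DIM = len(TIME_FEATURE_NAMES)


def hjorth(x: np.ndarray) -> tuple[float, float, float]:
    """Return (activity, mobility, complexity); (0, 0, 0) for flat input."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("Hjorth parameters need at least 3 samples")
    sx = x.std()
    if sx == 0:
        return 0.0, 0.0, 0.0
    d = np.diff(x)
    dd = np.diff(d)
    sd_, sdd = d.std(), dd.std()
    activity = float(sx**2)
    mobility = float(sd_ / sx)
    complexity = float((sdd / sd_) / (sd_ / sx)) if sd_ > 0 else 0.0
    return activity, mobility, complexity


def zero_crossings(x: np.ndarray) -> int:
    """Sign changes of the mean-removed signal; exact zeros are skipped."""
    y = np.asarray(x, dtype=float) - np.mean(x)
    s = np.sign(y)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[1:] != s[:-1]))


def decorrelation_time(x: np.ndarray) -> int:
    """Lag (samples) of the first non-positive biased autocorrelation.

    Lags are scanned incrementally (the first sign change is typically
    within a few samples for broadband signals), falling back to one FFT
    pass for slowly decorrelating inputs.
    """
    y = np.asarray(x, dtype=float) - np.mean(x)
    n = y.size
    c0 = float(y @ y)
    if c0 == 0:
        return 0
    for lag in range(1, min(n, 64)):
        if float(y[lag:] @ y[:-lag]) <= 0:
            return lag
    f = np.fft.rfft(y, 2 * n)
    acf = np.fft.irfft(f * np.conj(f))[:n]
    nonpos = np.flatnonzero(acf[64:] <= 0)
    return int(nonpos[0]) + 64 if nonpos.size else n


def time_features(x: np.ndarray, quantile: float = 0.75) -> np.ndarray:
    """The 12-dimensional time-domain vector for a single-channel series."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("time features need at least 3 samples")
    _, mobility, complexity = hjorth(x)
    sd = float(x.std())
    if sd == 0:
        skew = kurt = 0.0
    else:
        # biased moment estimators: m3/m2^1.5 and excess m4/m2^2 - 3
        y = x - x.mean()
        m2 = float(np.mean(y**2))
        skew = float(np.mean(y**3)) / m2**1.5
        kurt = float(np.mean(y**4)) / m2**2 - 3.0  # excess: Gaussian -> 0
    return np.array([
        sd,
        float(x.mean()),
        float(np.ptp(x)),
        skew,
        kurt,
        float(np.sqrt(np.mean(x**2))),
        mobility,
        float(np.quantile(x, quantile)),
        complexity,
        sd**2,
        float(decorrelation_time(x)),
        float(zero_crossings(x)),
    ])
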