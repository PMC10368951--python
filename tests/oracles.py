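"""Independent brute-force oracle implementations used only by tests.

Every function here is written directly from the defining formula with
plain loops (or the most literal vectorization), deliberately sharing no
code with the package, so agreement between package and oracle checks the
implementation rather than restating it.
"""

from __future__ import annotations

import math

import numpy as np


def hjorth_oracle(x):
    """Activity, mobility, complexity from the variance-ratio definitions."""
    x = np.asarray(x, dtype=float)
    d = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    dd = [d[i + 1] - d[i] for i in range(len(d) - 1)]

    def std(v):
        v = np.asarray(v)
        return math.sqrt(np.mean((v - v.mean()) ** 2))

    sx, sd_, sdd = std(x), std(d), std(dd)
    activity = sx**2
    mobility = sd_ / sx
    complexity = (sdd / sd_) / (sd_ / sx)
    return activity, mobility, complexity


def sampen_apen_oracle(x, m=2, r=None):
    """O(N^2) template matching, Chebyshev distance, match iff dist <= r.

    Same conventions as the package documents: SampEn over the first N-m
    templates at both lengths, pairs without self-matches; ApEn over
    N-m+1 / N-m templates with self-matches.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if r is None:
        r = 0.2 * math.sqrt(np.mean((x - x.mean()) ** 2))

    def templates(mm, count):
        return [x[i : i + mm] for i in range(count)]

    def cheb(a, b):
        return max(abs(u - v) for u, v in zip(a, b))

    # ApEn
    def phi(mm):
        temps = templates(mm, n - mm + 1)
        total = 0.0
        for a in temps:
            c = sum(1 for b in temps if cheb(a, b) <= r)
            total += math.log(c / len(temps))
        return total / len(temps)

    apen = phi(m) - phi(m + 1)

    # SampEn
    tm = templates(m, n - m)
    tm1 = templates(m + 1, n - m)
    bb = sum(
        1 for i in range(len(tm)) for j in range(i + 1, len(tm))
        if cheb(tm[i], tm[j]) <= r
    )
    aa = sum(
        1 for i in range(len(tm1)) for j in range(i + 1, len(tm1))
        if cheb(tm1[i], tm1[j]) <= r
    )
    if aa == 0 or bb == 0:
        sampen = math.log((n - m) * (n - m - 1)) - math.log(2.0)
    else:
        sampen = -math.log(aa / bb)
    return sampen, apen


def teager_kaiser_oracle(x):
    """psi(x[n]) = x[n]^2 - x[n-1]x[n+1], element by element."""
    x = np.asarray(x, dtype=float)
    return np.array([x[i] ** 2 - x[i - 1] * x[i + 1]
                     for i in range(1, len(x) - 1)])


def median_frequency_oracle(freqs, power, lo, hi):
    """First bin where the cumulative within-band power reaches half the
    band total, by explicit summation."""
    idx = [i for i, f in enumerate(freqs) if lo <= f < hi]
    total = sum(power[i] for i in idx)
    acc = 0.0
    for i in idx:
        acc += power[i]
        if acc >= total / 2.0:
            return freqs[i]
    return (lo + hi) / 2.0


def spectral_moment_oracle(freqs, power, k):
    """Trapezoidal integral of f^k P(f) by explicit summation."""
    total = 0.0
    for i in range(len(freqs) - 1):
        a = power[i] * freqs[i] ** k
        b = power[i + 1] * freqs[i + 1] ** k
        total += 0.5 * (a + b) * (freqs[i + 1] - freqs[i])
    return total


def naive_time_features(x, quantile=0.75):
    """Loop-based reimplementation of the 12 time-domain features."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    p2p = max(x) - min(x)
    if sd > 0:
        skew = (sum((v - mean) ** 3 for v in x) / n) / sd**3
        kurt = (sum((v - mean) ** 4 for v in x) / n) / sd**4 - 3.0
    else:
        skew = kurt = 0.0
    rms = math.sqrt(sum(v**2 for v in x) / n)
    _, mob, comp = hjorth_oracle(x) if sd > 0 else (0.0, 0.0, 0.0)
    q = float(np.quantile(x, quantile))
    # decorrelation time: first non-positive biased autocorrelation
    y = x - mean
    dct = n
    for lag in range(1, n):
        acf = sum(y[i] * y[i + lag] for i in range(n - lag))
        if acf <= 0:
            dct = lag
            break
    if sd == 0:
        dct = 0
    signs = [1 if v > 0 else (-1 if v < 0 else 0) for v in y]
    signs = [s for s in signs if s != 0]
    zc = sum(1 for i in range(1, len(signs)) if signs[i] != signs[i - 1])
    return np.array([sd, mean, p2p, skew, kurt, rms, mob, q, comp, var,
                     float(dct), float(zc)])
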