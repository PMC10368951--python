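"""Sixty-three non-linear-dynamics features per channel per epoch.

Layout (fixed order, totalling 63):

    Petrosian FD, line length, spectral entropy, Hurst exponent,
    sample entropy, Renyi entropy (10 sub-bands), Tsallis entropy (10),
    Shannon entropy (10), approximate entropy, SVD entropy,
    permutation entropy, Higuchi FD, wavelet entropy (7 per-level terms),
    Teager-Kaiser energy (mean, sd over 7 wavelet coefficient sets = 14),
    SVD Fisher information, DFA exponent, Katz FD.

The ten-dimensional entropy families are per-sub-band spectral entropies
over the same ten bands as median frequency, keeping one coherent band
scheme across the feature set. The Teager-Kaiser operator is

    psi(x[n]) = x[n]^2 - x[n-1] * x[n+1]

applied to each of the seven coefficient sets (approximation + 6 details,
coarse to fine) of a 6-level Daubechies decomposition.

Sample/approximate entropy use Chebyshev-distance template matching
(distance <= r counts as a match); neighbour counts come from a k-d tree,
which gives identical counts to the naive O(N^2) scan.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .features_freq import Spectrum, dwt_coeff_sets, psd
from .montage import MF_BANDS

NONLINEAR_FEATURE_NAMES: tuple[str, ...] = (
    ("petrosian_fd", "line_length", "spectral_entropy", "hurst", "sampen")
    + tuple(f"renyi_b{i}" for i in range(1, 11))
    + tuple(f"tsallis_b{i}" for i in range(1, 11))
    + tuple(f"shannon_b{i}" for i in range(1, 11))
    + ("apen", "svd_entropy", "perm_entropy", "higuchi_fd")
    + ("went_a6",) + tuple(f"went_d{j}" for j in range(6, 0, -1))
    + ("tk_mean_a6", "tk_std_a6")
    + tuple(f"tk_{s}_d{j}" for j in range(6, 0, -1) for s in ("mean", "std"))
    + ("svd_fisher", "dfa", "katz_fd")
)

NONLINEAR_DIM = len(NONLINEAR_FEATURE_NAMES)
assert NONLINEAR_DIM == 63


# ---------------------------------------------------------------------------
# Teager-Kaiser and wavelet entropy
# ---------------------------------------------------------------------------

def teager_kaiser(x: np.ndarray) -> np.ndarray:
    """psi(x[n]) = x[n]^2 - x[n-1]x[n+1] for interior samples."""
    x = np.asarray(x, dtype=float)
    return x[1:-1] ** 2 - x[:-2] * x[2:]


def teager_kaiser_features(x: np.ndarray, wavelet: str = "db4") -> np.ndarray:
    """Mean and sd of the Teager-Kaiser energy of each of the 7 wavelet
    coefficient sets, coarse to fine: 14 values."""
    sets = dwt_coeff_sets(x, wavelet)
    out = []
    for c in sets:
        if c.size < 3:
            raise ValueError(
                "Teager-Kaiser needs at least 3 coefficients per set"
            )
        tk = teager_kaiser(c)
        out.extend([float(tk.mean()), float(tk.std())])
    return np.array(out)


def wavelet_entropy_terms_from_energies(energies: np.ndarray) -> np.ndarray:
    """Per-level terms -p_j ln p_j of the wavelet energy distribution."""
    energies = np.asarray(energies, dtype=float)
    et = energies.sum()
    if et <= 0:
        raise ValueError("wavelet entropy undefined for zero-energy signal")
    p = energies / et
    terms = np.zeros_like(p)
    nz = p > 0
    terms[nz] = -p[nz] * np.log(p[nz])
    return terms


def wavelet_entropy(x: np.ndarray, wavelet: str = "db4") -> np.ndarray:
    """Seven per-level entropy terms over the 7 coefficient sets (their sum
    is the total wavelet entropy, at most ln 7)."""
    energies = np.array([float(np.sum(c**2))
                         for c in dwt_coeff_sets(x, wavelet)])
    return wavelet_entropy_terms_from_energies(energies)


# ---------------------------------------------------------------------------
# banded spectral entropy families
# ---------------------------------------------------------------------------

def entropy_family(spec: Spectrum, kind: str, q: float = 2.0) -> np.ndarray:
    """Entropy of the normalized within-band spectral distribution for each
    of the ten median-frequency sub-bands."""
    out = np.zeros(len(MF_BANDS))
    for i, (lo, hi) in enumerate(MF_BANDS):
        p = spec.power[spec.band_mask(lo, hi)]
        s = p.sum()
        if p.size == 0 or s <= 0:
            continue
        p = p / s
        nz = p[p > 0]
        if kind == "shannon":
            out[i] = float(-np.sum(nz * np.log(nz)))
        elif kind == "renyi":
            if abs(q - 1.0) < 1e-9:
                out[i] = float(-np.sum(nz * np.log(nz)))
            else:
                out[i] = float(np.log(np.sum(nz**q)) / (1.0 - q))
        elif kind == "tsallis":
            if abs(q - 1.0) < 1e-9:
                out[i] = float(-np.sum(nz * np.log(nz)))
            else:
                out[i] = float((1.0 - np.sum(nz**q)) / (q - 1.0))
        else:
            raise ValueError(f"unknown entropy kind {kind!r}")
    return out


# ---------------------------------------------------------------------------
# regularity entropies
# ---------------------------------------------------------------------------

def _embed(x: np.ndarray, m: int, delay: int = 1) -> np.ndarray:
    n = x.size - (m - 1) * delay
    idx = np.arange(n)[:, None] + delay * np.arange(m)[None, :]
    return x[idx]


@njit(cache=True)
def _template_match_counts(x: np.ndarray, m: int, r: float):
    """Chebyshev template-match counts over all pairs in one pass.

    Returns per-template match counts (self excluded) for lengths m and
    m+1, plus the pair counts restricted to the first n-m templates at
    length m and all n-m templates at length m+1.
    """
    n = x.size
    n_m = n - m + 1                 # templates of length m
    n_m1 = n - m                    # templates of length m+1
    cm = np.zeros(n_m, np.int64)
    cm1 = np.zeros(n_m1, np.int64)
    b_pairs = 0
    a_pairs = 0
    for i in range(n_m):
        for j in range(i + 1, n_m):
            ok = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    ok = False
                    break
            if ok:
                cm[i] += 1
                cm[j] += 1
                if j < n_m1:        # i < j, so i < n_m1 too
                    b_pairs += 1
                    if abs(x[i + m] - x[j + m]) <= r:
                        cm1[i] += 1
                        cm1[j] += 1
                        a_pairs += 1
    return cm, cm1, b_pairs, a_pairs


def regularity_entropies(x: np.ndarray, m: int = 2,
                         r: float | None = None) -> tuple[float, float]:
    """(sample entropy, approximate entropy) with tolerance r = 0.2 sd.

    Chebyshev distance, match means distance <= r. SampEn counts template
    pairs with self-matches excluded and both template lengths restricted
    to N-m vectors; ApEn averages per-template log frequencies with
    self-matches over the N-m+1 (length m) and N-m (length m+1) templates.
    A zero match count at length m+1 is guarded by the conventional upper
    bound ln((N-m)(N-m-1)) - ln 2.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("regularity entropies need at least 100 samples")
    sd = x.std()
    if sd == 0:
        return 0.0, 0.0
    if r is None:
        r = 0.2 * sd

    cm, cm1, b_pairs, a_pairs = _template_match_counts(x, m, float(r))
    # self-matches included for ApEn
    phi_m = float(np.mean(np.log((cm + 1) / cm.size)))
    phi_m1 = float(np.mean(np.log((cm1 + 1) / cm1.size)))
    apen = phi_m - phi_m1

    if b_pairs == 0 or a_pairs == 0:
        sampen = float(np.log((n - m) * (n - m - 1)) - np.log(2.0))
    else:
        sampen = float(-np.log(a_pairs / b_pairs))
    return sampen, apen


# ---------------------------------------------------------------------------
# fractal dimensions
# ---------------------------------------------------------------------------

def petrosian_fd(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    n = x.size
    d = np.diff(x)
    s = np.sign(d)
    s = s[s != 0]
    n_delta = int(np.sum(s[1:] != s[:-1])) if s.size > 1 else 0
    if n_delta == 0:
        return 1.0
    return float(np.log10(n) / (np.log10(n)
                                + np.log10(n / (n + 0.4 * n_delta))))


def higuchi_fd(x: np.ndarray, k_max: int = 10) -> float:
    x = np.asarray(x, dtype=float)
    n = x.size
    if x.std() == 0:
        return 1.0
    lk = np.empty(k_max)
    for k in range(1, k_max + 1):
        lm = []
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            if idx.size < 2:
                continue
            length = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((idx.size - 1) * k)
            lm.append(length * norm / k)
        lk[k - 1] = np.mean(lm)
    ks = np.arange(1, k_max + 1)
    slope, _ = np.polyfit(np.log(1.0 / ks), np.log(lk), 1)
    return float(slope)


def katz_fd(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    d = np.abs(np.diff(x))
    length = d.sum()
    if length == 0:
        return 1.0
    n = d.size
    extent = float(np.abs(x - x[0]).max())
    if extent == 0:
        return 1.0
    return float(np.log10(n) / (np.log10(n) + np.log10(extent / length)))


def fractal_dims(x: np.ndarray, k_max: int = 10) -> tuple[float, float, float]:
    """(Petrosian, Higuchi, Katz) fractal dimensions."""
    x = np.asarray(x, dtype=float)
    if x.size < 100:
        raise ValueError("fractal dimensions need at least 100 samples")
    return petrosian_fd(x), higuchi_fd(x, k_max), katz_fd(x)


# ---------------------------------------------------------------------------
# complexity miscellany
# ---------------------------------------------------------------------------

def spectral_entropy(spec: Spectrum) -> float:
    """Shannon entropy (nats) of the normalized full-band spectrum."""
    p = spec.power
    s = p.sum()
    if s <= 0:
        return 0.0
    p = p / s
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def _svd_probs(x: np.ndarray, dim: int = 10, delay: int = 1) -> np.ndarray:
    y = _embed(x, dim, delay)
    sv = np.linalg.svd(y, compute_uv=False)
    s = sv.sum()
    return sv / s if s > 0 else sv


def svd_entropy(x: np.ndarray, dim: int = 10, delay: int = 1) -> float:
    p = _svd_probs(x, dim, delay)
    nz = p[p > 0]
    if nz.size == 0:
        return 0.0
    return float(-np.sum(nz * np.log(nz)))


def svd_fisher(x: np.ndarray, dim: int = 10, delay: int = 1) -> float:
    p = _svd_probs(x, dim, delay)
    if p.size < 2 or p.sum() == 0:
        return 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (p[1:] - p[:-1]) ** 2 / np.where(p[:-1] > 0, p[:-1], np.inf)
    return float(np.sum(terms))


def permutation_entropy(x: np.ndarray, order: int = 3,
                        delay: int = 1) -> float:
    """Normalized ordinal-pattern entropy (0 for monotone input)."""
    x = np.asarray(x, dtype=float)
    patterns = np.argsort(_embed(x, order, delay), axis=1, kind="stable")
    codes = (patterns * (order ** np.arange(order))).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    return float(h / np.log(math.factorial(order)))


def hurst_rs(x: np.ndarray, n_sizes: int = 10) -> float:
    """Hurst exponent by rescaled-range analysis."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if x.std() == 0:
        return 0.5
    sizes = np.unique(np.floor(
        np.logspace(np.log10(10), np.log10(n // 2), n_sizes)
    ).astype(int))
    rs = []
    for s in sizes:
        k = n // s
        seg = x[: k * s].reshape(k, s)
        mean = seg.mean(axis=1, keepdims=True)
        z = np.cumsum(seg - mean, axis=1)
        r = z.max(axis=1) - z.min(axis=1)
        sdv = seg.std(axis=1)
        ok = sdv > 0
        if not ok.any():
            continue
        rs.append((s, float(np.mean(r[ok] / sdv[ok]))))
    if len(rs) < 2:
        return 0.5
    ls, lrs = np.log([a for a, _ in rs]), np.log([b for _, b in rs])
    slope, _ = np.polyfit(ls, lrs, 1)
    return float(slope)


def dfa_exponent(x: np.ndarray, n_sizes: int = 16,
                 min_box: int = 16) -> float:
    """Detrended fluctuation analysis scaling exponent (order-1 detrend,
    log-spaced box sizes between min_box and N/4)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if x.std() == 0:
        return 0.0
    profile = np.cumsum(x - x.mean())
    sizes = np.unique(np.floor(
        np.logspace(np.log10(min_box), np.log10(n // 4), n_sizes)
    ).astype(int))
    flucts = []
    for s in sizes:
        k = n // s
        seg = profile[: k * s].reshape(k, s)
        t = np.arange(s)
        # least-squares line per box, vectorized
        tm = t - t.mean()
        beta = (seg * tm).sum(axis=1) / (tm**2).sum()
        alpha = seg.mean(axis=1)
        resid = seg - (alpha[:, None] + beta[:, None] * tm)
        flucts.append((s, float(np.sqrt(np.mean(resid**2)))))
    ls = np.log([a for a, _ in flucts])
    lf = np.log([max(b, 1e-300) for _, b in flucts])
    slope, _ = np.polyfit(ls, lf, 1)
    return float(slope)


def line_length(x: np.ndarray) -> float:
    return float(np.abs(np.diff(np.asarray(x, dtype=float))).sum())


def complexity_misc(x: np.ndarray, fs: float = 250.0,
                    spec: Spectrum | None = None) -> tuple[float, ...]:
    """(spectral entropy, SVD entropy, SVD Fisher, permutation entropy,
    Hurst, DFA, line length)."""
    x = np.asarray(x, dtype=float)
    if x.size < 256:
        raise ValueError("complexity features need at least 256 samples")
    if spec is None:
        spec = psd(x, fs)
    return (
        spectral_entropy(spec),
        svd_entropy(x),
        svd_fisher(x),
        permutation_entropy(x),
        hurst_rs(x),
        dfa_exponent(x),
        line_length(x),
    )


def nonlinear_features(x: np.ndarray, fs: float = 250.0,
                       wavelet: str = "db4", q: float = 2.0,
                       spec: Spectrum | None = None) -> np.ndarray:
    """The 63-dimensional non-linear-dynamics vector for one channel epoch."""
    x = np.asarray(x, dtype=float)
    if spec is None:
        spec = psd(x, fs)
    spec_ent, svd_ent, svd_fish, perm_ent, hurst, dfa, ll = complexity_misc(
        x, fs, spec=spec
    )
    sampen, apen = regularity_entropies(x)
    pet, hig, katz = fractal_dims(x)
    if x.std() == 0:
        went = np.zeros(7)
        tk = np.zeros(14)
    else:
        went = wavelet_entropy(x, wavelet)
        tk = teager_kaiser_features(x, wavelet)
    return np.concatenate([
        [pet, ll, spec_ent, hurst, sampen],
        entropy_family(spec, "renyi", q),
        entropy_family(spec, "tsallis", q),
        entropy_family(spec, "shannon"),
        [apen, svd_ent, perm_ent, hig],
        went,
        tk,
        [svd_fish, dfa, katz],
    ])
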