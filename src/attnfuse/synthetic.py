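"""Paradigm-faithful synthetic EEG sessions and cohorts.

The recording paradigm is 20 trials of (3 s cue + 60 s task + 10 s rest) at
250 Hz over a 30-channel 10-20 montage, with exactly half the trials in the
attention state (serial mental arithmetic) and half in quiet eyes-open rest,
in randomized order.

Signal model: per channel, a sum of band-limited Gaussian noise components
(delta..gamma) whose relative powers follow a 1/f^a spectral envelope, a
configurable shared background across channels, and white sensor noise.
During attention task segments, the theta/alpha/beta component amplitudes on
prefrontal and occipital channels are scaled by band-specific gains below 1,
emulating the direction of the reduced activation seen in those regions.
Background RMS is ~10 microvolts so amplitude thresholds read naturally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_preprocess import Recording
from .montage import BANDS, CHANNELS_30, OCCIPITAL, PREFRONTAL


class SpecError(ValueError):
    """Invalid paradigm or effect specification."""


@dataclass(frozen=True)
class ParadigmSpec:
    """Timing, montage and sampling parameters of one recording session."""

    n_trials: int = 20
    cue_s: float = 3.0
    task_s: float = 60.0
    rest_s: float = 10.0
    fs: float = 250.0
    channels: tuple[str, ...] = CHANNELS_30

    def __post_init__(self) -> None:
        if self.n_trials <= 0 or self.n_trials % 2:
            raise SpecError("n_trials must be a positive even count")
        if min(self.cue_s, self.task_s, self.rest_s) <= 0 or self.fs <= 0:
            raise SpecError("durations and sampling rate must be positive")
        if not self.channels:
            raise SpecError("channel list must not be empty")
        if len(set(self.channels)) != len(self.channels):
            raise SpecError("channel labels must be unique")

    @property
    def trial_samples(self) -> int:
        return int(round((self.cue_s + self.task_s + self.rest_s) * self.fs))

    @property
    def task_samples(self) -> int:
        return int(round(self.task_s * self.fs))

    @property
    def cue_samples(self) -> int:
        return int(round(self.cue_s * self.fs))

    @property
    def session_samples(self) -> int:
        return self.n_trials * self.trial_samples


def _default_gains() -> dict[str, float]:
    return {"theta": 0.7, "alpha": 0.7, "beta": 0.7}


@dataclass(frozen=True)
class EffectSpec:
    """Controllable state effect and noise structure of the generator.

    ``band_gain`` are multiplicative *power* factors applied to the listed
    bands on ``affected_channels`` during attention task segments; values
    below 1 reproduce the attention-lower-than-rest direction. Gains of 1
    everywhere disable the effect (null sessions).
    """

    band_gain: dict[str, float] = field(default_factory=_default_gains)
    affected_channels: tuple[str, ...] = PREFRONTAL + OCCIPITAL
    noise_exponent: float = 1.0
    artifact_rate: float = 0.0          # transients per minute
    subject_gain_sd: float = 0.1        # inter-subject log-gain dispersion
    shared_background: float = 0.3      # variance fraction common to channels
    background_rms_uv: float = 10.0
    sensor_noise_uv: float = 1.0
    # Optional planted connectivity effect: during task segments of
    # ``fc_state`` trials, channel fc_edge[0]'s fc_band component is mixed
    # with channel fc_edge[1]'s by variance fraction fc_strength.
    fc_edge: tuple[str, str] | None = None
    fc_band: str = "theta"
    fc_strength: float = 0.0
    fc_state: str = "non_attention"

    def __post_init__(self) -> None:
        for band, g in self.band_gain.items():
            if band not in BANDS:
                raise SpecError(f"unknown band {band!r}")
            if g <= 0:
                raise SpecError("band gains must be positive")
        if not 0 <= self.shared_background < 1:
            raise SpecError("shared_background must be in [0, 1)")
        if self.artifact_rate < 0 or self.subject_gain_sd < 0:
            raise SpecError("rates and dispersions must be non-negative")
        if not 0 <= self.fc_strength < 1:
            raise SpecError("fc_strength must be in [0, 1)")

    @property
    def enabled(self) -> bool:
        return any(g != 1.0 for g in self.band_gain.values())


@dataclass
class SyntheticSession:
    """One generated subject session plus its ground truth."""

    recording: Recording
    ground_truth: tuple[str, ...]
    seed: int
    subject_id: str = "S0"
    effect: EffectSpec | None = None    # effective (possibly jittered) spec


def _band_weights(nfft: int, fs: float, lo: float, hi: float,
                  exponent: float) -> np.ndarray:
    """Spectral weights for unit-variance noise confined to [lo, hi) with a
    1/f^a envelope. For interior rfft bins with complex unit-Gaussian
    amplitudes, E[var] = 4 * sum(w^2) / nfft^2, so weights are scaled by the
    inverse square root of that."""
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    mask = (freqs >= lo) & (freqs < hi)
    w = np.zeros(freqs.size)
    w[mask] = freqs[mask] ** (-exponent / 2.0)
    e = 4.0 * np.sum(w**2) / nfft**2
    return w / np.sqrt(e) if e > 0 else w


def _shaped_noise(rng: np.random.Generator, nfft: int, n: int,
                  w: np.ndarray) -> np.ndarray:
    """Gaussian noise with spectral amplitude profile ``w`` (frequency-domain
    synthesis on an FFT-friendly padded length, truncated to ``n``)."""
    z = rng.standard_normal(w.size) + 1j * rng.standard_normal(w.size)
    return np.fft.irfft(z * w, n=nfft)[:n]


def generate_subject(paradigm: ParadigmSpec | None = None,
                     effect: EffectSpec | None = None,
                     seed: int = 0,
                     subject_id: str = "S0") -> SyntheticSession:
    """Generate one session; bit-identical for identical arguments.

    Annotations mark the task-segment onset of every trial with its state.
    """
    paradigm = paradigm or ParadigmSpec()
    effect = effect or EffectSpec()
    rng = np.random.default_rng(seed)

    n_ch = len(paradigm.channels)
    n = paradigm.session_samples
    fs = paradigm.fs

    states = np.array(
        ["attention"] * (paradigm.n_trials // 2)
        + ["non_attention"] * (paradigm.n_trials // 2)
    )
    rng.shuffle(states)

    # Band weights ~ integral of the 1/f^a envelope over each band.
    weights = {}
    for band, (lo, hi) in BANDS.items():
        a = effect.noise_exponent
        weights[band] = np.log(hi / lo) if abs(a - 1) < 1e-12 else (
            (hi ** (1 - a) - lo ** (1 - a)) / (1 - a)
        )
    total = sum(weights.values())
    amp = {b: effect.background_rms_uv * np.sqrt(w / total)
           for b, w in weights.items()}

    task_slices = []
    for t in range(paradigm.n_trials):
        a0 = t * paradigm.trial_samples + paradigm.cue_samples
        task_slices.append(slice(a0, a0 + paradigm.task_samples))

    affected_idx = [i for i, ch in enumerate(paradigm.channels)
                    if ch in effect.affected_channels]
    rho = effect.shared_background
    fc_active = effect.fc_edge is not None and effect.fc_strength > 0

    # Bands sharing the same gain envelope (and no connectivity mixing) are
    # synthesized jointly: disjoint spectral supports make the combined
    # component distributionally identical to the sum of per-band noises.
    from scipy.fft import next_fast_len

    nfft = next_fast_len(n)
    groups: list[tuple[tuple, list[str]]] = []
    for band in BANDS:
        is_fc = fc_active and band == effect.fc_band
        key = (effect.band_gain.get(band, 1.0), is_fc)
        for k, members in groups:
            if k == key:
                members.append(band)
                break
        else:
            groups.append((key, [band]))

    signal = np.zeros((n_ch, n))
    for (gain, is_fc), members in groups:
        w = np.zeros(nfft // 2 + 1)
        for band in members:
            lo, hi = BANDS[band]
            w += amp[band] * _band_weights(nfft, fs, lo, hi,
                                           effect.noise_exponent)
        shared = _shaped_noise(rng, nfft, n, w)
        comp = np.empty((n_ch, n))
        for c in range(n_ch):
            own = _shaped_noise(rng, nfft, n, w)
            comp[c] = np.sqrt(1 - rho) * own + np.sqrt(rho) * shared
        if gain != 1.0 and affected_idx:
            scale = np.sqrt(gain)
            for t, sl in enumerate(task_slices):
                if states[t] == "attention":
                    comp[affected_idx, sl.start : sl.stop] *= scale
        if is_fc:
            try:
                ia = paradigm.channels.index(effect.fc_edge[0])
                ib = paradigm.channels.index(effect.fc_edge[1])
            except ValueError as exc:
                raise SpecError("fc_edge channels must be in the montage") from exc
            k = effect.fc_strength
            for t, sl in enumerate(task_slices):
                if states[t] == effect.fc_state:
                    comp[ia, sl] = (np.sqrt(1 - k) * comp[ia, sl]
                                    + np.sqrt(k) * comp[ib, sl])
        signal += comp

    signal += effect.sensor_noise_uv * rng.standard_normal((n_ch, n))

    if effect.artifact_rate > 0:
        minutes = n / fs / 60.0
        n_art = rng.poisson(effect.artifact_rate * minutes)
        width = int(round(0.5 * fs))
        shape = np.sin(np.pi * np.arange(width) / width)
        for _ in range(n_art):
            c = rng.integers(n_ch)
            t0 = rng.integers(0, n - width)
            a = rng.uniform(300.0, 500.0) * rng.choice([-1.0, 1.0])
            signal[c, t0 : t0 + width] += a * shape

    annotations = [(sl.start, paradigm.task_samples, states[t])
                   for t, sl in enumerate(task_slices)]
    rec = Recording(signal=signal, fs=fs, channel_names=paradigm.channels,
                    annotations=annotations)
    return SyntheticSession(recording=rec, ground_truth=tuple(states),
                            seed=seed, subject_id=subject_id, effect=effect)


def generate_cohort(n_subjects: int,
                    paradigm: ParadigmSpec | None = None,
                    effect: EffectSpec | None = None,
                    seed: int = 0) -> list[SyntheticSession]:
    """Generate a cohort with per-subject effect-gain variability.

    Each subject's band gains are the cohort gains jittered by a log-normal
    factor with standard deviation ``subject_gain_sd`` (0 makes all subjects
    share identical effect parameters). Subject seeds derive reproducibly
    from the master seed.
    """
    if n_subjects < 2:
        raise SpecError("a cohort needs at least 2 subjects (LOSO undefined)")
    paradigm = paradigm or ParadigmSpec()
    effect = effect or EffectSpec()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    sessions = []
    for i, child in enumerate(children):
        sub_rng = np.random.default_rng(child)
        jitter = {
            b: g * float(np.exp(sub_rng.normal(0.0, effect.subject_gain_sd)))
            for b, g in effect.band_gain.items()
        }
        sub_effect = replace(effect, band_gain=jitter)
        sub_seed = int(sub_rng.integers(0, 2**31 - 1))
        sessions.append(
            generate_subject(paradigm, sub_effect, seed=sub_seed,
                             subject_id=f"S{i:02d}")
        )
    return sessions
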