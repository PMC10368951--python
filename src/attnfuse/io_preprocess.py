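"""Recording I/O, band-pass filtering, epoching and artifact rejection.

A :class:`Recording` holds a channels x samples matrix in microvolts with
trial annotations; the preprocessing chain is

    read_recording -> bandpass_fir -> segment_epochs -> reject_artifacts

Each 60-s task segment is cut into six contiguous 10-s epochs (2,500
samples at 250 Hz), the unit of all downstream feature extraction.

Two on-disk containers are supported: a compressed NumPy array with a JSON
sidecar of metadata, and 16-bit EDF+ (read through :mod:`mne`; written by a
minimal EDF+C writer with a single annotation channel).
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .montage import STATES

#: Samples per epoch at the paradigm's 250 Hz sampling rate (10 s).
EPOCH_SAMPLES = 2500
#: Samples per task segment (60 s) and epochs it divides into.
TASK_SAMPLES = 15000
EPOCHS_PER_TRIAL = 6


class RecordingError(ValueError):
    """Malformed recording container or inconsistent annotations."""


@dataclass
class Recording:
    """Multichannel EEG block in microvolts with trial annotations.

    Annotations are ``(onset_sample, duration_samples, state)`` triples
    marking task-segment onsets; sample indexing is 0-based, intervals
    half-open.
    """

    signal: np.ndarray          # (n_channels, n_samples), microvolts
    fs: float
    channel_names: tuple[str, ...]
    annotations: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise RecordingError("signal must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise RecordingError("sampling rate must be positive")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.signal.shape[0]:
            raise RecordingError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signal.shape[0]} signal rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise RecordingError("channel names must be unique")
        n = self.signal.shape[1]
        for onset, dur, state in self.annotations:
            if onset < 0 or dur <= 0 or onset + dur > n:
                raise RecordingError(
                    f"annotation ({onset}, {dur}, {state!r}) outside signal "
                    f"bounds [0, {n})"
                )
            if state not in STATES:
                raise RecordingError(f"unknown state label {state!r}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class Epoch:
    """One labelled fixed-length window (channels x 2,500 samples)."""

    data: np.ndarray
    state: str
    subject_id: str
    trial_index: int
    epoch_index: int            # 0..5 within the trial


@dataclass
class EpochSet:
    """Chronologically ordered epochs plus an artifact-rejection log."""

    epochs: list[Epoch]
    rejection_log: list[tuple[int, int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.epochs)

    def states(self) -> np.ndarray:
        return np.array([e.state for e in self.epochs])

    def stack(self) -> np.ndarray:
        """Return data as an (n_epochs, n_channels, n_samples) array."""
        return np.stack([e.data for e in self.epochs])


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path, format: str = "array") -> Path:
    """Write a recording to ``path`` in the given container format.

    ``array`` writes ``<path>.npz`` (or ``path`` if it already ends in
    ``.npz``) plus a ``.json`` sidecar; ``edf`` writes 16-bit EDF+C.
    """
    path = Path(path)
    if format == "array":
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        np.savez_compressed(path, signal=rec.signal)
        sidecar = {
            "fs": rec.fs,
            "channel_names": list(rec.channel_names),
            "annotations": [[int(o), int(d), s] for o, d, s in rec.annotations],
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        return path
    if format == "edf":
        if path.suffix.lower() != ".edf":
            path = path.with_suffix(".edf")
        _write_edf(rec, path)
        return path
    raise RecordingError(f"unknown format {format!r} (expected 'array' or 'edf')")


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from an array container or an EDF file.

    The format is inferred from the suffix when not given.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "array"
    if format == "array":
        if not path.exists():
            raise RecordingError(f"no such file: {path}")
        with np.load(path) as npz:
            sig = npz["signal"]
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise RecordingError(f"missing JSON sidecar for {path}")
        meta = json.loads(sidecar_path.read_text())
        return Recording(
            signal=sig,
            fs=float(meta["fs"]),
            channel_names=tuple(meta["channel_names"]),
            annotations=[(int(o), int(d), str(s)) for o, d, s in meta["annotations"]],
        )
    if format == "edf":
        return _read_edf(path)
    raise RecordingError(f"unknown format {format!r} (expected 'array' or 'edf')")


def _fmt8(value: float) -> bytes:
    """Format a number into EDF's 8-byte ASCII numeric field."""
    for fmt in ("%.2f", "%.1f", "%.0f"):
        s = fmt % value
        if len(s) <= 8:
            return s.ljust(8).encode("ascii")
    raise RecordingError(f"value {value} does not fit an EDF numeric field")


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF+C writer: 1-s records, 16-bit, one annotation channel."""
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise RecordingError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    n_records = int(np.ceil(rec.n_samples / spr))
    n_sig = rec.n_channels + 1          # + EDF Annotations
    ann_samples = 60                    # 120 bytes of TAL space per record

    absmax = np.maximum(np.abs(rec.signal).max(axis=1), 1.0)
    # Round the bounds to their 8-char header representation so the
    # quantization gain matches what a reader reconstructs from the header.
    absmax = np.array([float(_fmt8(np.ceil(v * 100) / 100)) for v in absmax])
    pmin, pmax = -absmax, absmax
    dmin, dmax = -32768, 32767

    hdr = b""
    hdr += b"0".ljust(8)
    hdr += b"X X X X".ljust(80)
    hdr += b"Startdate 01-JAN-2024 X X X".ljust(80)
    hdr += b"01.01.24" + b"00.00.00"
    hdr += str(256 * (n_sig + 1)).ljust(8).encode()
    hdr += b"EDF+C".ljust(44)
    hdr += str(n_records).ljust(8).encode()
    hdr += b"1".ljust(8)
    hdr += str(n_sig).ljust(4).encode()

    labels = [n[:16].ljust(16).encode() for n in rec.channel_names]
    labels.append(b"EDF Annotations ")
    hdr += b"".join(labels)
    hdr += b" " * 80 * n_sig                                  # transducer
    hdr += b"".join([b"uV".ljust(8)] * rec.n_channels) + b" " * 8
    hdr += b"".join(_fmt8(v) for v in pmin) + _fmt8(-1)
    hdr += b"".join(_fmt8(v) for v in pmax) + _fmt8(1)
    hdr += b"".join([b"-32768".ljust(8)] * n_sig)
    hdr += b"".join([b"32767".ljust(8)] * n_sig)
    hdr += b" " * 80 * n_sig                                  # prefilter
    hdr += b"".join([str(spr).ljust(8).encode()] * rec.n_channels)
    hdr += str(ann_samples).ljust(8).encode()
    hdr += b" " * 32 * n_sig

    gain = (pmax - pmin) / (dmax - dmin)
    offset = (pmax + pmin) / 2.0

    # Group annotations by the record their onset falls into.
    by_record: dict[int, list[tuple[int, int, str]]] = {}
    for onset, dur, state in rec.annotations:
        by_record.setdefault(int(onset // spr), []).append((onset, dur, state))

    padded = np.zeros((rec.n_channels, n_records * spr))
    padded[:, : rec.n_samples] = rec.signal
    digital = np.clip(
        np.round((padded - offset[:, None]) / gain[:, None]), dmin, dmax
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_records):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
            tal = f"+{r}\x14\x14\x00".encode()
            for onset, dur, state in by_record.get(r, []):
                tal += (
                    f"+{onset / fs:.4f}\x15{dur / fs:.4f}"
                    f"\x14{state}\x14\x00".encode()
                )
            tal = tal + b"\x00" * (2 * ann_samples - len(tal))
            if len(tal) > 2 * ann_samples:
                raise RecordingError("annotation text overflows EDF record")
            fh.write(tal)


def _read_edf(path: Path) -> Recording:
    import mne

    if not Path(path).exists():
        raise RecordingError(f"no such file: {path}")
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sig = raw.get_data() * 1e6          # volts -> microvolts
    fs = float(raw.info["sfreq"])
    annotations = []
    for onset, dur, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        if desc not in STATES:
            continue
        annotations.append((int(round(onset * fs)), int(round(dur * fs)), desc))
    return Recording(
        signal=sig,
        fs=fs,
        channel_names=tuple(raw.ch_names),
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def design_bandpass(low: float, high: float, fs: float,
                    numtaps: int | None = None) -> np.ndarray:
    """Windowed-sinc (Hamming) band-pass FIR taps.

    The default order targets a 0.5 Hz transition width at the low edge
    (Hamming transition ~= 3.3 / N normalized), giving 1,651 taps at 250 Hz.
    """
    if not (0 < low < high < fs / 2):
        raise RecordingError(
            f"band ({low}, {high}) must satisfy 0 < low < high < fs/2 = {fs / 2}"
        )
    if numtaps is None:
        numtaps = int(np.ceil(3.3 * fs / 0.5))
        numtaps += 1 - numtaps % 2      # force odd (type I, integer delay)
    return sps.firwin(numtaps, [low, high], pass_zero=False, fs=fs,
                      window="hamming")


def bandpass_fir(rec: Recording, low: float = 0.5, high: float = 50.0,
                 numtaps: int | None = None) -> Recording:
    """Zero-phase FIR band-pass of every channel; annotations untouched.

    The symmetric (linear-phase) filter is applied in a single FFT pass with
    centred output, so the group delay is exactly compensated.
    """
    taps = design_bandpass(low, high, rec.fs, numtaps)
    filtered = sps.fftconvolve(rec.signal, taps[None, :], mode="same", axes=1)
    return replace(rec, signal=filtered, annotations=list(rec.annotations))


def segment_epochs(rec: Recording, subject_id: str = "S0") -> EpochSet:
    """Cut every annotated task segment into 6 contiguous 10-s epochs.

    Cue and rest samples are discarded: only the 60-s task window of each
    trial is epoched, inheriting the trial's state label.
    """
    task_samples = int(round(60.0 * rec.fs))
    epoch_samples = task_samples // EPOCHS_PER_TRIAL
    epochs: list[Epoch] = []
    for trial_index, (onset, dur, state) in enumerate(rec.annotations):
        if dur < task_samples:
            raise RecordingError(
                f"trial {trial_index}: task segment has {dur} samples, "
                f"needs {task_samples}"
            )
        for k in range(EPOCHS_PER_TRIAL):
            a = onset + k * epoch_samples
            epochs.append(
                Epoch(
                    data=rec.signal[:, a : a + epoch_samples].copy(),
                    state=state,
                    subject_id=subject_id,
                    trial_index=trial_index,
                    epoch_index=k,
                )
            )
    return EpochSet(epochs=epochs)


def reject_artifacts(es: EpochSet, amp_threshold: float = 100.0,
                     myo_zscore: float | None = None) -> EpochSet:
    """Drop epochs whose peak absolute amplitude exceeds ``amp_threshold``.

    Optionally also flags "myoelectric" epochs whose 30-50 Hz power is more
    than ``myo_zscore`` standard deviations above the set's mean (disabled
    by default). Survivors keep chronological order; dropped epochs are
    logged as ``(trial_index, epoch_index, reason)``.
    """
    if amp_threshold <= 0:
        raise RecordingError("amplitude threshold must be positive")
    keep: list[Epoch] = []
    log: list[tuple[int, int, str]] = list(es.rejection_log)
    myo_flags = _myo_flags(es, myo_zscore) if myo_zscore else None
    for i, ep in enumerate(es.epochs):
        peak = float(np.abs(ep.data).max())
        if peak > amp_threshold:
            log.append((ep.trial_index, ep.epoch_index,
                        f"peak amplitude {peak:.1f} uV > {amp_threshold} uV"))
        elif myo_flags is not None and myo_flags[i]:
            log.append((ep.trial_index, ep.epoch_index,
                        "high-frequency (30-50 Hz) power outlier"))
        else:
            keep.append(ep)
    if es.epochs and not keep:
        raise RecordingError(
            f"all {len(es.epochs)} epochs rejected at threshold "
            f"{amp_threshold} uV; review the threshold"
        )
    return EpochSet(epochs=keep, rejection_log=log)


def _myo_flags(es: EpochSet, z: float) -> np.ndarray:
    from .features_freq import psd

    hp = np.empty(len(es.epochs))
    for i, ep in enumerate(es.epochs):
        p = 0.0
        for ch in ep.data:
            spec = psd(ch, fs=250.0)
            sel = (spec.freqs >= 30) & (spec.freqs < 50)
            p += float(np.trapezoid(spec.power[sel], spec.freqs[sel]))
        hp[i] = p / ep.data.shape[0]
    mu, sd = hp.mean(), hp.std()
    if sd == 0:
        return np.zeros(len(hp), dtype=bool)
    return (hp - mu) / sd > z
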