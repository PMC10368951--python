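"""Channel montage and canonical frequency-band definitions.

The 30-channel scalp montage follows the international 10-20 layout used
throughout the package; every channel subset elsewhere (affected channels,
reduced analysis montages) must be drawn from this list.
"""

from __future__ import annotations

#: 30-channel montage, fixed order (frontal to occipital rows).
CHANNELS_30: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

#: Lateral-prefrontal and occipital channels: the scalp regions where the
#: attention state shows reduced band power relative to quiet rest.
PREFRONTAL: tuple[str, ...] = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")
OCCIPITAL: tuple[str, ...] = ("O1", "Oz", "O2")

#: Canonical EEG rhythms (Hz), half-open [lo, hi).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}
BAND_NAMES: tuple[str, ...] = tuple(BANDS)

#: Connectivity band scheme: alpha split into lower (8-10 Hz) and upper
#: (10-13 Hz) sub-bands, as is conventional in attention studies.
FC_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "lower_alpha": (8.0, 10.0),
    "upper_alpha": (10.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}

#: Ten sub-bands used for median frequency and the banded entropy families.
MF_BANDS: tuple[tuple[float, float], ...] = (
    (0.5, 2.0), (2.0, 4.0), (4.0, 5.0), (5.0, 7.0), (7.0, 10.0),
    (10.0, 13.0), (13.0, 15.0), (15.0, 20.0), (20.0, 30.0), (30.0, 40.0),
)

STATES: tuple[str, str] = ("attention", "non_attention")
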