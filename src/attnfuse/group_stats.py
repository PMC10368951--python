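"""Group-level analyses: state-averaged feature t-tests, band-limited
functional-connectivity contrasts with FDR correction, Z-scored band-power
topographies, and Morlet time-frequency maps.

The group pipeline mirrors the within-cohort analysis of an attention
study: per subject, epoch features are averaged per state after a 3-SD
outlier exclusion; paired two-sided t-tests across subjects then contrast
attention against non-attention per channel and feature. Connectivity is
Pearson correlation between band-filtered channel pairs per epoch, averaged
within subject and state, with Benjamini-Hochberg correction of the
edge-wise paired tests at q = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features_freq import band_filter_sos
from .fusion_classify import DesignMatrix
from .io_preprocess import EpochSet
from .montage import BAND_NAMES, FC_BANDS, STATES


# ---------------------------------------------------------------------------
# state means and paired feature tests
# ---------------------------------------------------------------------------

def subject_state_means(dm: DesignMatrix, n_sd: float = 3.0) -> pd.DataFrame:
    """Mean of every feature per (subject, state) after outlier removal.

    Epoch values deviating more than ``n_sd`` standard deviations from the
    subject-state mean of that feature are excluded (single pass). Raises
    if a subject-state cell loses all its epochs.
    """
    X = dm.X
    frames = {}
    for subject in np.unique(dm.subject):
        for state in STATES:
            sel = (dm.subject == subject) & (dm.y == state)
            if not sel.any():
                raise ValueError(f"subject {subject!r} has no {state!r} epochs")
            vals = X.loc[sel].to_numpy()
            mu = vals.mean(axis=0)
            sd = vals.std(axis=0)
            keep = np.abs(vals - mu) <= n_sd * np.where(sd > 0, sd, np.inf)
            if not keep.any(axis=0).all():
                raise ValueError(
                    f"outlier rule removed every epoch for subject "
                    f"{subject!r}, state {state!r}"
                )
            with np.errstate(invalid="ignore"):
                m = np.where(keep, vals, np.nan)
            frames[(subject, state)] = np.nanmean(m, axis=0)
    out = pd.DataFrame(frames, index=X.columns).T
    out.index = pd.MultiIndex.from_tuples(out.index, names=["subject", "state"])
    return out


def paired_feature_ttests(means: pd.DataFrame) -> pd.DataFrame:
    """Channels x features matrix of paired t-test p-values.

    ``means`` is the frame from :func:`subject_state_means`; columns are
    ``CH:FEATURE``. Zero-variance differences are guarded with p = 1.
    """
    att = means.xs("attention", level="state")
    non = means.xs("non_attention", level="state")
    non = non.loc[att.index]
    if len(att) < 3:
        raise ValueError("paired feature tests need at least 3 subjects")
    d = att.to_numpy() - non.to_numpy()
    t, p = stats.ttest_rel(att.to_numpy(), non.to_numpy(), axis=0)
    p = np.where(d.std(axis=0) == 0, 1.0, p)
    p = np.nan_to_num(p, nan=1.0)
    cols = means.columns
    channels = list(dict.fromkeys(c.split(":", 1)[0] for c in cols))
    features = list(dict.fromkeys(c.split(":", 1)[1] for c in cols))
    mat = pd.DataFrame(index=channels, columns=features, dtype=float)
    for c, pv in zip(cols, p):
        ch, feat = c.split(":", 1)
        mat.loc[ch, feat] = pv
    return mat


# ---------------------------------------------------------------------------
# functional connectivity
# ---------------------------------------------------------------------------

def connectivity_fc(es: EpochSet, fs: float = 250.0,
                    bands: dict[str, tuple[float, float]] = FC_BANDS
                    ) -> dict[str, dict[str, np.ndarray]]:
    """Per band and state: channel correlation matrix averaged over epochs.

    Pearson correlation between band-filtered channel pairs is computed per
    epoch and averaged within each state. Constant channels contribute a
    guarded 0 off-diagonal. Matrices are symmetric with unit diagonal.
    """
    data = es.stack()                       # (n_epochs, n_ch, n_samples)
    if data.shape[1] < 2:
        raise ValueError("connectivity needs at least 2 channels")
    states = es.states()
    out: dict[str, dict[str, np.ndarray]] = {}
    for band, (lo, hi) in bands.items():
        filt = sps.sosfiltfilt(band_filter_sos(lo, hi, fs), data, axis=-1)
        mats = {state: [] for state in STATES}
        for i in range(data.shape[0]):
            x = filt[i]
            sd = x.std(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                c = np.corrcoef(x)
            c = np.nan_to_num(c, nan=0.0)
            np.fill_diagonal(c, 1.0)
            c[sd == 0, :] = 0.0
            c[:, sd == 0] = 0.0
            np.fill_diagonal(c, 1.0)
            if states[i] in mats:
                mats[states[i]].append(c)
        out[band] = {
            state: (np.mean(m, axis=0) if m
                    else np.eye(data.shape[1]))
            for state, m in mats.items()
        }
    return out


@dataclass
class FCContrast:
    """Edge-wise paired-test results for one band."""

    raw_p: np.ndarray           # (n_ch, n_ch), symmetric, diag 1
    adj_p: np.ndarray
    mask: np.ndarray            # boolean, significant after FDR


def fc_group_test(fc_att: list[np.ndarray], fc_nonatt: list[np.ndarray],
                  q: float = 0.05) -> FCContrast:
    """Paired t-tests across subjects per edge, BH-corrected at ``q``.

    Inputs are per-subject state-averaged FC matrices for one band. The
    returned mask is symmetric with a False diagonal.
    """
    if len(fc_att) != len(fc_nonatt) or len(fc_att) < 3:
        raise ValueError("paired FC tests need >= 3 matched subjects")
    a = np.stack(fc_att)
    b = np.stack(fc_nonatt)
    n_ch = a.shape[1]
    iu = np.triu_indices(n_ch, k=1)
    diffs = a[:, iu[0], iu[1]] - b[:, iu[0], iu[1]]
    t, p = stats.ttest_rel(a[:, iu[0], iu[1]], b[:, iu[0], iu[1]], axis=0)
    p = np.where(diffs.std(axis=0) == 0, 1.0, np.nan_to_num(p, nan=1.0))
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    raw = np.ones((n_ch, n_ch))
    adj = np.ones((n_ch, n_ch))
    mask = np.zeros((n_ch, n_ch), dtype=bool)
    raw[iu], adj[iu], mask[iu] = p, p_adj, reject
    raw[(iu[1], iu[0])], adj[(iu[1], iu[0])] = p, p_adj
    mask[(iu[1], iu[0])] = reject
    return FCContrast(raw_p=raw, adj_p=adj, mask=mask)


def fc_group_test_bands(cohort_fc: list[dict[str, dict[str, np.ndarray]]],
                        q: float = 0.05) -> dict[str, FCContrast]:
    """Run :func:`fc_group_test` for every band of a cohort's FC maps."""
    bands = cohort_fc[0].keys()
    return {
        band: fc_group_test(
            [subj[band]["attention"] for subj in cohort_fc],
            [subj[band]["non_attention"] for subj in cohort_fc],
            q=q,
        )
        for band in bands
    }


# ---------------------------------------------------------------------------
# topographies and time-frequency maps
# ---------------------------------------------------------------------------

def band_topography(dm: DesignMatrix) -> pd.DataFrame:
    """Mean Z-scored band power per band, channel and state.

    Band-power columns are Z-scored per subject, band and channel across
    that subject's epochs (zero-variance features give Z = 0), then
    averaged per state across all epochs and subjects. Returns a frame
    indexed by (band, channel) with one column per state.
    """
    bp_cols = [c for c in dm.X.columns
               if c.split(":", 1)[1].startswith("bandpower_")]
    if not bp_cols:
        raise ValueError("design matrix has no band-power columns")
    z = np.empty((len(dm.X), len(bp_cols)))
    vals = dm.X[bp_cols].to_numpy()
    for subject in np.unique(dm.subject):
        sel = dm.subject == subject
        v = vals[sel]
        mu, sd = v.mean(axis=0), v.std(axis=0)
        z[sel] = np.where(sd > 0, (v - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    rows = []
    for j, col in enumerate(bp_cols):
        ch, feat = col.split(":", 1)
        band = feat.removeprefix("bandpower_")
        row = {"band": band, "channel": ch}
        for state in STATES:
            row[state] = float(z[dm.y == state, j].mean())
        rows.append(row)
    out = pd.DataFrame(rows).set_index(["band", "channel"])
    return out.loc[[b for b in BAND_NAMES if b in out.index.levels[0]]]


@dataclass
class TFRMap:
    """Time-frequency power map for one channel."""

    freqs: np.ndarray
    times: np.ndarray
    power: np.ndarray           # (n_freqs, n_times), non-negative

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency axis must be ascending")


def morlet_tfr(x: np.ndarray, fs: float,
               freqs: np.ndarray | None = None,
               n_cycles: float = 7.0) -> TFRMap:
    """Morlet-wavelet time-frequency power of a single-channel signal.

    Default frequency grid is 1-50 Hz in 1 Hz steps with 7 cycles at every
    frequency.
    """
    from mne.time_frequency import tfr_array_morlet

    x = np.asarray(x, dtype=float)
    if freqs is None:
        freqs = np.arange(1.0, 51.0)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.min() <= 0 or freqs.max() >= fs / 2:
        raise ValueError(f"frequencies must lie in (0, {fs / 2})")
    power = tfr_array_morlet(
        x[None, None, :], sfreq=fs, freqs=freqs, n_cycles=n_cycles,
        output="power", verbose="error",
    )[0, 0]
    times = np.arange(x.size) / fs
    return TFRMap(freqs=freqs, times=times, power=power)
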