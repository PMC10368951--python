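"""Group statistics: outlier-robust state means, paired feature tests,
band-limited connectivity with FDR control, topographies and Morlet maps."""

import numpy as np
import pandas as pd
import pytest

from attnfuse.fusion_classify import DesignMatrix
from attnfuse.group_stats import (band_topography, connectivity_fc,
                                  fc_group_test, fc_group_test_bands,
                                  morlet_tfr, paired_feature_ttests,
                                  subject_state_means)
from attnfuse.io_preprocess import Epoch, EpochSet
from attnfuse.montage import FC_BANDS

FS = 250.0


def tiny_design(values_by_subject, feature="Cz:bandpower_alpha"):
    """One-column design matrix; half the epochs per subject per state."""
    rows, y, subj = [], [], []
    for sid, (att, non) in values_by_subject.items():
        for v in att:
            rows.append(v); y.append("attention"); subj.append(sid)
        for v in non:
            rows.append(v); y.append("non_attention"); subj.append(sid)
    n = len(rows)
    return DesignMatrix(
        X=pd.DataFrame({feature: rows}),
        y=np.array(y), subject=np.array(subj),
        trial=np.zeros(n, dtype=int), epoch=np.zeros(n, dtype=int),
    )


def make_epochset(data, states):
    """EpochSet from an (n_epochs, n_ch, n_samples) array."""
    return EpochSet(epochs=[
        Epoch(data=d, state=s, subject_id="S0", trial_index=i // 6,
              epoch_index=i % 6)
        for i, (d, s) in enumerate(zip(data, states))
    ])


# ---------------------------------------------------------------------------
# state means and paired tests
# ---------------------------------------------------------------------------

def test_outlier_rule_excludes_single_extreme_epoch():
    att = [1.0] * 19 + [100.0]           # one gross outlier
    dm = tiny_design({"s0": (att, [2.0] * 20)})
    means = subject_state_means(dm)
    assert means.loc[("s0", "attention")].iloc[0] == pytest.approx(1.0)
    assert means.loc[("s0", "non_attention")].iloc[0] == pytest.approx(2.0)


def test_state_means_keep_all_epochs_without_outliers():
    rng = np.random.default_rng(0)
    att = rng.normal(5, 1, 24)
    dm = tiny_design({"s0": (list(att), [0.0] * 24)})
    means = subject_state_means(dm)
    assert means.loc[("s0", "attention")].iloc[0] == pytest.approx(att.mean())


def test_state_means_missing_state_rejected():
    dm = tiny_design({"s0": ([1.0, 2.0], [])})
    with pytest.raises(ValueError, match="no"):
        subject_state_means(dm)


def test_paired_ttests_detect_planted_effect_and_guard_ties():
    rng = np.random.default_rng(1)
    subjects = {}
    for i in range(8):
        base = rng.normal(10, 0.5)
        att = list(rng.normal(base - 2.0, 0.2, 10))   # planted decrease
        non = list(rng.normal(base, 0.2, 10))
        subjects[f"s{i}"] = (att, non)
    dm = tiny_design(subjects)
    # add a zero-variance column: identical in both states
    dm.X["Cz:std"] = 1.0
    pmat = paired_feature_ttests(subject_state_means(dm))
    assert pmat.shape == (1, 2)                       # 1 channel x 2 features
    assert pmat.loc["Cz", "bandpower_alpha"] < 0.01
    assert pmat.loc["Cz", "std"] == 1.0


def test_paired_ttests_need_three_subjects():
    dm = tiny_design({"s0": ([1.0] * 4, [2.0] * 4),
                      "s1": ([1.5] * 4, [2.5] * 4)})
    with pytest.raises(ValueError, match="3 subjects"):
        paired_feature_ttests(subject_state_means(dm))


# ---------------------------------------------------------------------------
# functional connectivity
# ---------------------------------------------------------------------------

def test_fc_duplicated_channel_has_unit_correlation():
    rng = np.random.default_rng(2)
    base = rng.standard_normal((12, 1, 2500))
    data = np.concatenate([base, base, rng.standard_normal((12, 1, 2500))],
                          axis=1)
    es = make_epochset(data, ["attention", "non_attention"] * 6)
    fc = connectivity_fc(es, FS, bands={"alpha": (8.0, 13.0)})
    for state in ("attention", "non_attention"):
        m = fc["alpha"][state]
        assert m.shape == (3, 3)
        np.testing.assert_allclose(m, m.T, atol=1e-12)        # symmetric
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert m[0, 1] == pytest.approx(1.0, abs=1e-9)        # duplicate


def test_fc_independent_channels_near_zero_and_constant_guard():
    rng = np.random.default_rng(3)
    data = rng.standard_normal((20, 3, 2500))
    data[:, 2, :] = 0.0         # flat channel stays flat after filtering
    es = make_epochset(data, ["attention", "non_attention"] * 10)
    fc = connectivity_fc(es, FS)
    assert set(fc) == set(FC_BANDS)
    m = fc["lower_alpha"]["attention"]
    assert abs(m[0, 1]) < 0.1
    # the constant channel row is guarded to zero off-diagonal
    assert m[2, 0] == 0.0 and m[2, 2] == 1.0


def test_fc_single_channel_rejected():
    es = make_epochset(np.zeros((2, 1, 2500)), ["attention", "non_attention"])
    with pytest.raises(ValueError, match="2 channels"):
        connectivity_fc(es, FS)


def test_fc_group_test_null_and_planted_edge():
    rng = np.random.default_rng(4)
    n_sub, n_ch = 12, 5
    base = rng.uniform(-0.2, 0.2, size=(n_sub, n_ch, n_ch))
    att = (base + base.transpose(0, 2, 1)) / 2
    noise = rng.normal(0, 0.02, size=att.shape)
    non = att + (noise + noise.transpose(0, 2, 1)) / 2
    # plant a consistent decrease on edge (0, 3)
    att[:, 0, 3] -= 0.5
    att[:, 3, 0] -= 0.5
    res = fc_group_test(list(att), list(non), q=0.05)
    assert res.mask[0, 3] and res.mask[3, 0]
    assert not res.mask.diagonal().any()
    np.testing.assert_array_equal(res.mask, res.mask.T)
    iu = np.triu_indices(n_ch, k=1)
    assert np.all(res.adj_p[iu] >= res.raw_p[iu] - 1e-12)    # BH never lowers
    assert res.raw_p[0, 3] < 0.001


def test_fc_group_test_needs_matched_subjects():
    mats = [np.eye(3)] * 2
    with pytest.raises(ValueError, match="subjects"):
        fc_group_test(mats, mats)


def test_fc_group_test_bands_runs_per_band():
    rng = np.random.default_rng(5)

    def one_subject():
        out = {}
        for band in ("theta", "lower_alpha"):
            out[band] = {}
            for state in ("attention", "non_attention"):
                a = rng.uniform(-0.1, 0.1, (4, 4))
                m = (a + a.T) / 2
                np.fill_diagonal(m, 1.0)
                out[band][state] = m
        return out

    cohort = [one_subject() for _ in range(6)]
    res = fc_group_test_bands(cohort)
    assert set(res) == {"theta", "lower_alpha"}
    # null cohort: FDR keeps discoveries at ~zero
    assert sum(r.mask.sum() for r in res.values()) <= 2


# ---------------------------------------------------------------------------
# topography
# ---------------------------------------------------------------------------

def test_topography_planted_alpha_decrease_is_negative(small_design):
    topo = band_topography(small_design)
    assert set(topo.columns) == {"attention", "non_attention"}
    diff = topo["attention"] - topo["non_attention"]
    # the synthetic effect suppresses alpha on the affected channels
    for ch in ("Fp1", "Fp2", "O1", "Oz"):
        assert diff.loc[("alpha", ch)] < 0
    # per-band, per-channel means of a within-subject Z-score average out
    assert abs(topo.to_numpy().mean()) < 0.2


def test_topography_requires_band_power_columns():
    dm = tiny_design({"s0": ([1.0] * 4, [2.0] * 4)}, feature="Cz:std")
    with pytest.raises(ValueError, match="band-power"):
        band_topography(dm)


def test_topography_zero_variance_gives_zero_z():
    dm = tiny_design({"s0": ([3.0] * 6, [3.0] * 6)})
    topo = band_topography(dm)
    assert topo.loc[("alpha", "Cz"), "attention"] == 0.0
    assert topo.loc[("alpha", "Cz"), "non_attention"] == 0.0


# ---------------------------------------------------------------------------
# Morlet time-frequency maps
# ---------------------------------------------------------------------------

def test_morlet_ridge_at_tone_frequency():
    # 30 s of signal: the 7-cycle wavelet at 1 Hz needs > 11 s of support
    t = np.arange(7500) / FS
    x = np.sin(2 * np.pi * 11.0 * t)
    tfr = morlet_tfr(x, FS)
    assert tfr.power.shape == (50, 7500)
    mid = tfr.power[:, 2000:5500]                     # away from edges
    ridge = tfr.freqs[np.argmax(mid.mean(axis=1))]
    assert ridge == pytest.approx(11.0, abs=1.0)
    assert np.all(tfr.power >= 0)


def test_morlet_zero_signal_and_frequency_validation():
    tfr = morlet_tfr(np.zeros(1000), FS, freqs=np.arange(5.0, 20.0))
    assert np.allclose(tfr.power, 0.0)
    with pytest.raises(ValueError, match="frequencies"):
        morlet_tfr(np.zeros(1000), FS, freqs=np.array([1.0, 200.0]))
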