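"""Fusion vector layout, design-matrix construction, chronological and
leave-one-subject-out cross-validation, and classifier configurations."""

import numpy as np
import pytest

from attnfuse.features_freq import FREQ_FEATURE_NAMES
from attnfuse.features_nonlinear import NONLINEAR_FEATURE_NAMES
from attnfuse.features_time import TIME_FEATURE_NAMES
from attnfuse.fusion_classify import (BLOCKS, FUSION_DIM,
                                      FUSION_FEATURE_NAMES, CVResult,
                                      DesignMatrix, build_design_matrix,
                                      chronological_folds,
                                      compare_feature_blocks, fuse,
                                      intra_subject_cv, loso_cv,
                                      make_classifier, paired_ttest)
from attnfuse.io_preprocess import Epoch, EpochSet
from attnfuse.synthetic import ParadigmSpec, generate_subject
from conftest import MONTAGE6, STRONG_EFFECT, session_to_epochs


@pytest.fixture(scope="module")
def second_design():
    """A second full-feature design matrix for LOSO and block comparison."""
    session = generate_subject(ParadigmSpec(channels=MONTAGE6),
                               STRONG_EFFECT, seed=12, subject_id="S1")
    return build_design_matrix(session_to_epochs(session), fs=250.0,
                               channel_names=MONTAGE6)


# ---------------------------------------------------------------------------
# fusion vector
# ---------------------------------------------------------------------------

def test_fusion_layout_is_123_in_block_order():
    assert FUSION_DIM == 123
    assert len(TIME_FEATURE_NAMES) == 12
    assert len(FREQ_FEATURE_NAMES) == 48
    assert len(NONLINEAR_FEATURE_NAMES) == 63
    assert FUSION_FEATURE_NAMES[:12] == TIME_FEATURE_NAMES
    assert FUSION_FEATURE_NAMES[12:60] == FREQ_FEATURE_NAMES
    assert FUSION_FEATURE_NAMES[60:] == NONLINEAR_FEATURE_NAMES
    assert len(set(FUSION_FEATURE_NAMES)) == 123       # no name collisions


def test_fuse_preserves_values_and_order():
    t = np.arange(12.0)
    f = np.arange(100.0, 148.0)
    d = np.arange(200.0, 263.0)
    v = fuse(t, f, d)
    assert v.shape == (123,)
    np.testing.assert_array_equal(v, np.concatenate([t, f, d]))


def test_fuse_rejects_wrong_block_lengths():
    with pytest.raises(ValueError):
        fuse(np.zeros(11), np.zeros(48), np.zeros(63))
    with pytest.raises(ValueError):
        fuse(np.zeros(12), np.zeros(48), np.zeros(62))


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def test_design_matrix_shape_and_column_naming(small_design):
    assert small_design.X.shape == (120, 6 * 123)
    assert list(small_design.X.columns[:2]) == ["Fp1:std", "Fp1:mean"]
    assert small_design.X.columns[123] == "Fp2:std"
    assert (small_design.y == "attention").sum() == 60
    assert np.all(np.isfinite(small_design.X.to_numpy()))


def test_block_subsets_select_the_right_columns(small_design):
    t = small_design.subset(("time",))
    f = small_design.subset(("freq",))
    n = small_design.subset(("nonlinear",))
    assert t.X.shape == (120, 6 * 12)
    assert f.X.shape == (120, 6 * 48)
    assert n.X.shape == (120, 6 * 63)
    all_cols = set(t.X.columns) | set(f.X.columns) | set(n.X.columns)
    assert all_cols == set(small_design.X.columns)


def test_single_block_matrix_matches_fusion_subset(small_epochset,
                                                   small_design):
    dm_t = build_design_matrix(small_epochset, fs=250.0, blocks=("time",),
                               channel_names=MONTAGE6)
    sub = small_design.subset(("time",))
    np.testing.assert_allclose(dm_t.X.to_numpy(), sub.X[dm_t.X.columns],
                               rtol=1e-12)


def test_design_matrix_metadata_length_mismatch_rejected(small_design):
    with pytest.raises(ValueError, match="length mismatch"):
        DesignMatrix(small_design.X, small_design.y[:-1],
                     small_design.subject, small_design.trial,
                     small_design.epoch)


def test_empty_epoch_set_rejected():
    with pytest.raises(ValueError, match="empty"):
        build_design_matrix(EpochSet(epochs=[]))


@pytest.mark.filterwarnings("ignore::RuntimeWarning")
def test_non_finite_feature_reported_with_location():
    data = np.zeros((1, 2500))
    data[0, :10] = np.inf
    es = EpochSet(epochs=[Epoch(data=data, state="attention",
                                subject_id="s0", trial_index=3,
                                epoch_index=1)])
    with pytest.raises(ValueError, match="trial 3 epoch 1"):
        build_design_matrix(es, blocks=("time",))


# ---------------------------------------------------------------------------
# chronological folds
# ---------------------------------------------------------------------------

def test_chronological_folds_partition_contiguous_remainder_last():
    folds = chronological_folds(123, 5)
    assert [len(f) for f in folds] == [24, 24, 24, 24, 27]
    np.testing.assert_array_equal(np.concatenate(folds), np.arange(123))
    for f in folds:
        np.testing.assert_array_equal(np.diff(f), 1)   # contiguous in time


def test_chronological_folds_exact_division():
    folds = chronological_folds(120, 5)
    assert all(len(f) == 24 for f in folds)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def test_classifier_configurations():
    rf = make_classifier("rf")
    assert rf.n_estimators == 100 and rf.criterion == "gini"
    dt = make_classifier("dt")
    assert dt.criterion == "entropy" and dt.splitter == "best"
    svm = make_classifier("svm")
    assert svm.named_steps["svc"].kernel == "linear"
    assert svm.named_steps["svc"].C == 2.0
    with pytest.raises(ValueError):
        make_classifier("knn")


def test_svm_scaler_fits_on_training_data_only():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((60, 4))
    X[40:] += 50.0                       # "test" rows have a huge offset
    y = np.array(["a", "b"] * 30)
    pipe = make_classifier("svm")
    pipe.fit(X[:40], y[:40])
    np.testing.assert_allclose(pipe.named_steps["scale"].mean_,
                               X[:40].mean(axis=0), atol=1e-12)


# ---------------------------------------------------------------------------
# cross-validation protocols
# ---------------------------------------------------------------------------

def test_intra_cv_is_deterministic_and_separates_strong_effect(small_design):
    r1 = intra_subject_cv(small_design, "rf", seed=0)
    r2 = intra_subject_cv(small_design, "rf", seed=0)
    assert r1.accuracies == r2.accuracies
    assert len(r1.accuracies) == 5
    assert r1.units == [f"fold{i}" for i in range(5)]
    assert r1.mean > 0.8


def test_permuted_labels_give_chance_accuracy(small_design):
    rng = np.random.default_rng(99)
    shuffled = DesignMatrix(small_design.X, rng.permutation(small_design.y),
                            small_design.subject, small_design.trial,
                            small_design.epoch)
    acc = intra_subject_cv(shuffled.subset(("time",)), "rf", seed=0).mean
    assert 0.35 <= acc <= 0.65


def test_intra_cv_rejects_single_class_training_fold(small_design):
    bad = DesignMatrix(small_design.X, np.array(["attention"] * 120),
                       small_design.subject, small_design.trial,
                       small_design.epoch)
    with pytest.raises(ValueError, match="class"):
        intra_subject_cv(bad, "dt")


def test_loso_holds_each_subject_out_once(small_design, second_design):
    res = loso_cv([small_design, second_design], "dt", seed=0)
    assert len(res.accuracies) == 2
    assert all(0.0 <= a <= 1.0 for a in res.accuracies)
    assert len(set(res.units)) == 2
    with pytest.raises(ValueError, match="2 subjects"):
        loso_cv([small_design])


def test_compare_feature_blocks_layout(small_design, second_design):
    results, pvalues = compare_feature_blocks([small_design, second_design],
                                              clf_names=("dt",))
    assert set(results["block"]) == set(BLOCKS) | {"fusion"}
    assert len(results) == 4
    assert ((results["mean"] >= 0) & (results["mean"] <= 1)).all()
    assert len(pvalues) == 3
    assert ((pvalues["p_value"] >= 0) & (pvalues["p_value"] <= 1)).all()


def test_paired_ttest_zero_variance_guard_and_symmetry():
    a = np.array([0.8, 0.9, 0.7, 0.85])
    assert paired_ttest(a, a) == 1.0
    assert paired_ttest(a, a + 0.1) == pytest.approx(
        paired_ttest(a + 0.1, a))


def test_cvresult_summary_round_trip():
    r = CVResult(accuracies=[0.8, 0.9], classifier="rf", units=["f0", "f1"])
    d = r.as_dict()
    assert d["mean"] == pytest.approx(0.85)
    assert d["std"] == pytest.approx(0.05)
    assert d["clf"] == "rf" and d["units"] == ["f0", "f1"]
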