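"""Feature fusion, design matrices and the two cross-validation protocols.

The fused vector is the order-preserving concatenation of the time (12),
frequency (48) and non-linear (63) blocks: 123 named scalars per channel.
Per epoch, per-channel vectors are concatenated channel-major into one row
of the design matrix (30 channels x 123 = 3,690 columns for the full
montage), with column names ``CH:FEATURE``.

Classification protocols:

* intra-subject: chronological 5-fold CV -- the epoch sequence is split
  into contiguous blocks strictly in time order, each serving once as the
  test set;
* inter-subject: leave-one-subject-out (LOSO) CV.

Classifier configurations: random forest with 100 trees and Gini impurity;
decision tree with entropy criterion and best splitter; linear-kernel SVM
with C = 2 (the configured kernel coefficient 0.2 is recorded but inert for
a linear kernel). Features are standardized with training-fold statistics
before the SVM only; trees receive raw features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features_freq import FREQ_FEATURE_NAMES, psd, freq_features
from .features_nonlinear import NONLINEAR_FEATURE_NAMES, nonlinear_features
from .features_time import TIME_FEATURE_NAMES, time_features
from .io_preprocess import EpochSet

BLOCKS: tuple[str, ...] = ("time", "freq", "nonlinear")

BLOCK_NAMES: dict[str, tuple[str, ...]] = {
    "time": TIME_FEATURE_NAMES,
    "freq": FREQ_FEATURE_NAMES,
    "nonlinear": NONLINEAR_FEATURE_NAMES,
}

#: The 123 fused feature names, block order fixed: time, freq, nonlinear.
FUSION_FEATURE_NAMES: tuple[str, ...] = (
    TIME_FEATURE_NAMES + FREQ_FEATURE_NAMES + NONLINEAR_FEATURE_NAMES
)
FUSION_DIM = len(FUSION_FEATURE_NAMES)

SVM_KERNEL_COEF = 0.2   # recorded configuration value; inert for linear kernel


def fuse(t: np.ndarray, f: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Concatenate the three feature blocks into the 123-dim fusion vector."""
    t, f, d = (np.asarray(v, dtype=float) for v in (t, f, d))
    if t.shape != (len(TIME_FEATURE_NAMES),):
        raise ValueError(f"time block must have {len(TIME_FEATURE_NAMES)} values")
    if f.shape != (len(FREQ_FEATURE_NAMES),):
        raise ValueError(f"freq block must have {len(FREQ_FEATURE_NAMES)} values")
    if d.shape != (len(NONLINEAR_FEATURE_NAMES),):
        raise ValueError(
            f"nonlinear block must have {len(NONLINEAR_FEATURE_NAMES)} values"
        )
    return np.concatenate([t, f, d])


@dataclass
class DesignMatrix:
    """Stacked epoch-by-feature table with labels and grouping metadata."""

    X: pd.DataFrame                     # columns "CH:FEATURE", rows chronological
    y: np.ndarray                       # state labels (strings)
    subject: np.ndarray
    trial: np.ndarray
    epoch: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.X)
        for name in ("y", "subject", "trial", "epoch"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"metadata array {name!r} length mismatch")

    def block_columns(self, blocks: set[str] | tuple[str, ...]) -> list[str]:
        wanted = set()
        for b in blocks:
            wanted.update(BLOCK_NAMES[b])
        return [c for c in self.X.columns if c.split(":", 1)[1] in wanted]

    def subset(self, blocks) -> "DesignMatrix":
        return DesignMatrix(self.X[self.block_columns(blocks)], self.y,
                            self.subject, self.trial, self.epoch)


def extract_epoch_features(data: np.ndarray, fs: float,
                           blocks=BLOCKS) -> np.ndarray:
    """Per-channel features for one epoch, concatenated channel-major."""
    rows = []
    for ch in data:
        parts = []
        spec = psd(ch, fs) if ("freq" in blocks or "nonlinear" in blocks) else None
        if "time" in blocks:
            parts.append(time_features(ch))
        if "freq" in blocks:
            parts.append(freq_features(ch, fs, spec=spec))
        if "nonlinear" in blocks:
            parts.append(nonlinear_features(ch, fs, spec=spec))
        rows.append(np.concatenate(parts))
    return np.concatenate(rows)


def build_design_matrix(es: EpochSet, fs: float = 250.0,
                        blocks=BLOCKS,
                        channel_names: tuple[str, ...] | None = None
                        ) -> DesignMatrix:
    """Compute selected feature blocks per channel per epoch.

    Raises a descriptive error if any feature comes out non-finite.
    """
    if not es.epochs:
        raise ValueError("cannot build a design matrix from an empty epoch set")
    blocks = tuple(b for b in BLOCKS if b in blocks)
    n_ch = es.epochs[0].data.shape[0]
    if channel_names is None:
        channel_names = tuple(f"ch{c}" for c in range(n_ch))
    feat_names = tuple(n for b in blocks for n in BLOCK_NAMES[b])
    columns = [f"{ch}:{name}" for ch in channel_names for name in feat_names]

    rows = np.empty((len(es.epochs), len(columns)))
    for i, ep in enumerate(es.epochs):
        rows[i] = extract_epoch_features(ep.data, fs, blocks)
        if not np.all(np.isfinite(rows[i])):
            j = int(np.flatnonzero(~np.isfinite(rows[i]))[0])
            raise ValueError(
                f"non-finite feature {columns[j]!r} in trial "
                f"{ep.trial_index} epoch {ep.epoch_index}"
            )
    return DesignMatrix(
        X=pd.DataFrame(rows, columns=columns),
        y=np.array([e.state for e in es.epochs]),
        subject=np.array([e.subject_id for e in es.epochs]),
        trial=np.array([e.trial_index for e in es.epochs]),
        epoch=np.array([e.epoch_index for e in es.epochs]),
    )


@dataclass
class CVResult:
    """Per-fold or per-held-out-subject accuracies with summary stats."""

    accuracies: list[float]
    classifier: str
    block: str = "fusion"
    units: list[str] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std(self) -> float:
        return float(np.std(self.accuracies))

    def as_dict(self) -> dict:
        return {
            "clf": self.classifier, "block": self.block,
            "per_unit": list(map(float, self.accuracies)),
            "units": list(self.units),
            "mean": self.mean, "std": self.std,
        }


def make_classifier(name: str, seed: int = 0):
    """RF (100 trees, Gini), DT (entropy, best) or linear SVM (C=2)."""
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, criterion="gini",
                                      random_state=seed)
    if name == "dt":
        return DecisionTreeClassifier(criterion="entropy", splitter="best",
                                      random_state=seed)
    if name == "svm":
        return Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="linear", C=2.0)),
        ])
    raise ValueError(f"unknown classifier {name!r} (expected rf, dt or svm)")


def chronological_folds(n: int, k: int = 5) -> list[np.ndarray]:
    """Split 0..n-1 into k contiguous blocks; remainder goes to the last."""
    base = n // k
    bounds = [i * base for i in range(k)] + [n]
    return [np.arange(bounds[i], bounds[i + 1]) for i in range(k)]


def intra_subject_cv(dm: DesignMatrix, clf_name: str = "rf", n_folds: int = 5,
                     seed: int = 0) -> CVResult:
    """Chronological k-fold CV on one subject's epoch sequence."""
    X = dm.X.to_numpy()
    y = dm.y
    n = len(y)
    folds = chronological_folds(n, n_folds)
    accs = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(
                f"fold {i}: a class is absent from the training split; "
                "review stratification"
            )
        clf = make_classifier(clf_name, seed)
        clf.fit(X[train_idx], y[train_idx])
        accs.append(float(np.mean(clf.predict(X[test_idx]) == y[test_idx])))
    return CVResult(accuracies=accs, classifier=clf_name,
                    units=[f"fold{i}" for i in range(len(folds))])


def loso_cv(cohort: list[DesignMatrix], clf_name: str = "rf",
            seed: int = 0) -> CVResult:
    """Leave-one-subject-out CV over a cohort of design matrices."""
    if len(cohort) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    accs, units = [], []
    Xs = [dm.X.to_numpy() for dm in cohort]
    ys = [dm.y for dm in cohort]
    for held in range(len(cohort)):
        X_train = np.vstack([x for i, x in enumerate(Xs) if i != held])
        y_train = np.concatenate([y for i, y in enumerate(ys) if i != held])
        clf = make_classifier(clf_name, seed)
        clf.fit(X_train, y_train)
        accs.append(float(np.mean(clf.predict(Xs[held]) == ys[held])))
        units.append(str(cohort[held].subject[0]))
    return CVResult(accuracies=accs, classifier=clf_name, units=units)


def compare_feature_blocks(cohort: list[DesignMatrix],
                           clf_names=("rf", "dt", "svm"),
                           n_folds: int = 5, seed: int = 0
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intra-subject accuracies for each feature block and classifier.

    Returns (results, pvalues): one CVResult summary per block x classifier
    (mean over subjects of the per-subject 5-fold mean), and paired t-test
    p-values comparing fusion against each single block per classifier.
    """
    block_sets = {b: (b,) for b in BLOCKS}
    block_sets["fusion"] = BLOCKS
    per_subject: dict[tuple[str, str], list[float]] = {}
    for block, members in block_sets.items():
        for clf_name in clf_names:
            key = (block, clf_name)
            per_subject[key] = [
                intra_subject_cv(dm.subset(members), clf_name, n_folds, seed).mean
                for dm in cohort
            ]
    rows = [
        {"block": b, "clf": c,
         "mean": float(np.mean(v)), "std": float(np.std(v))}
        for (b, c), v in per_subject.items()
    ]
    pv_rows = []
    for clf_name in clf_names:
        fusion = np.array(per_subject[("fusion", clf_name)])
        for b in BLOCKS:
            other = np.array(per_subject[(b, clf_name)])
            pv_rows.append({
                "clf": clf_name, "block": b,
                "p_value": paired_ttest(fusion, other),
            })
    return pd.DataFrame(rows), pd.DataFrame(pv_rows)


def paired_ttest(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided paired t-test; zero-variance differences give p = 1."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.allclose(d.std(), 0):
        return 1.0
    return float(stats.ttest_rel(a, b).pvalue)
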