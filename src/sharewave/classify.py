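"""SMOTE-balanced linear-SVM decoding of the sharing decision.

Features are the trial's liking rating, the log theta power at the
electrodes where theta differed between conditions, the log alpha power
at the electrodes where alpha differed, and the frontal alpha asymmetry
index.  The minority ("share") class is oversampled with SMOTE —
synthetic points placed uniformly at random on segments between a
minority sample and one of its k = 5 nearest minority neighbors — and a
soft-margin SVM with a linear kernel (C = 1) is evaluated in 10-fold
cross-validation with per-class precision/recall/F1 and overall
accuracy.

Two cross-validation orderings are offered.  ``smote_mode="paper"``
balances the *whole* table first and then splits (with 316 + 1099 trials
this yields the 1978/220 train/test partition sizes), which leaks
synthetic copies of test information into training and therefore
overstates performance; ``smote_mode="leakfree"`` splits first and
oversamples within each training fold only.  The paper ordering is the
default for fidelity; the leak is real and documented.

Classifier significance uses label-permutation (does the observed CV
accuracy beat accuracies under shuffled labels?), and two feature sets
are compared with a paired t-test on per-trial correctness over the same
held-out trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FeatureTable",
    "ClassifierConfig",
    "ClassReport",
    "CVReport",
    "smote_oversample",
    "kfold_split",
    "fit_predict_svm",
    "evaluate",
    "cross_validate",
    "permutation_significance",
    "compare_models",
    "THETA_FEATURE_ELECTRODES",
    "ALPHA_FEATURE_ELECTRODES",
]

#: Electrode sets whose band power differed between conditions, used as
#: the default EEG feature columns.
THETA_FEATURE_ELECTRODES = ("F3", "Fz", "F4", "P8", "P4", "O2")
ALPHA_FEATURE_ELECTRODES = ("Fz", "F4", "O2")

MINORITY = "share"
MAJORITY = "noshare"


@dataclass
class FeatureTable:
    """Trials x named features with binary share/noshare labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.y):
            raise ValueError("X must be (n_trials, n_features) aligned with y")
        if not np.isfinite(self.X).all():
            raise ValueError("missing/non-finite feature values")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if len(np.unique(self.y)) != 2:
            raise ValueError("both classes must be present")

    def select(self, names: tuple[str, ...]) -> "FeatureTable":
        cols = [self.feature_names.index(n) for n in names]
        return FeatureTable(self.X[:, cols], self.y, tuple(names))


@dataclass(frozen=True)
class ClassifierConfig:
    C: float = 1.0
    kernel: str = "linear"
    k_smote: int = 5
    n_folds: int = 10
    n_perm: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.k_smote < 1 or self.n_folds < 2:
            raise ValueError("invalid classifier configuration")


@dataclass
class ClassReport:
    precision: float
    recall: float
    f1: float
    support: int
    degenerate: bool = False   # a zero-denominator metric was reported as 0


@dataclass
class CVReport:
    per_class: dict[str, ClassReport]
    accuracy: float
    macro_f1: float
    fold_assignment: np.ndarray
    predictions: np.ndarray
    truth: np.ndarray
    fold_train_sizes: list[int] = field(default_factory=list)
    fold_test_sizes: list[int] = field(default_factory=list)
    synthetic_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote_oversample(minority: np.ndarray, n_new: int, k: int = 5,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority rows by nearest-neighbor interpolation.

    Each synthetic row is ``x_i + u (x_nn - x_i)`` with u ~ Uniform(0,1),
    x_i a random minority row and x_nn one of its k nearest minority
    neighbors (Euclidean, self excluded).  Returns ``(rows, parents)``
    where ``parents[j] = (i, nn)`` records the two source rows of
    synthetic row j.  Deterministic per seed.
    """
    minority = np.asarray(minority, dtype=float)
    m = minority.shape[0]
    if m <= k:
        raise ValueError(f"minority size {m} must exceed k = {k}")
    if n_new == 0:
        return np.empty((0, minority.shape[1])), np.empty((0, 2), dtype=int)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority)
    _, idx = nn.kneighbors(minority)        # column 0 is the point itself
    neigh = idx[:, 1:k + 1]
    rng = np.random.default_rng(seed)
    base = rng.integers(0, m, size=n_new)
    pick = neigh[base, rng.integers(0, k, size=n_new)]
    u = rng.uniform(0.0, 1.0, size=n_new)
    rows = minority[base] + u[:, None] * (minority[pick] - minority[base])
    return rows, np.column_stack([base, pick])


def balance_with_smote(table: FeatureTable, k: int = 5, seed: int = 0
                       ) -> tuple[FeatureTable, np.ndarray]:
    """SMOTE the minority class up to the majority count.

    Returns the balanced table and a boolean mask marking synthetic rows.
    """
    n_min = int(np.sum(table.y == MINORITY))
    n_maj = int(np.sum(table.y == MAJORITY))
    n_new = n_maj - n_min
    rows, _parents = smote_oversample(table.X[table.y == MINORITY],
                                      n_new, k=k, seed=seed)
    X = np.vstack([table.X, rows])
    y = np.concatenate([table.y, np.full(n_new, MINORITY)])
    synth = np.concatenate([np.zeros(len(table.y), bool),
                            np.ones(n_new, bool)])
    return FeatureTable(X, y, table.feature_names), synth


# ---------------------------------------------------------------------------
# cross-validation machinery
# ---------------------------------------------------------------------------

def kfold_split(n: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Random fold assignment: disjoint folds covering all samples,
    sizes differing by at most 1.  Deterministic per seed."""
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for f, s in enumerate(sizes):
        folds[order[start:start + s]] = f
        start += s
    return folds


def fit_predict_svm(train_X: np.ndarray, train_y: np.ndarray,
                    test_X: np.ndarray, config: ClassifierConfig
                    ) -> np.ndarray:
    """Standardize on the training rows, fit a linear SVM, predict.

    Feature means/SDs come from the training set only.  Raises on a
    single-class training set.
    """
    if len(np.unique(train_y)) < 2:
        raise ValueError("training set contains a single class")
    scaler = StandardScaler().fit(train_X)
    clf = SVC(kernel=config.kernel, C=config.C, random_state=config.seed)
    clf.fit(scaler.transform(train_X), train_y)
    return clf.predict(scaler.transform(test_X))


def evaluate(preds: np.ndarray, truth: np.ndarray) -> CVReport:
    """Per-class precision/recall/F1 and overall accuracy.

    A zero denominator reports the metric as 0 and flags the class
    report as degenerate.
    """
    preds = np.asarray(preds)
    truth = np.asarray(truth)
    if len(preds) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    classes = sorted(set(truth) | set(preds))
    per_class = {}
    f1s = []
    for cls in classes:
        tp = int(np.sum((preds == cls) & (truth == cls)))
        fp = int(np.sum((preds == cls) & (truth != cls)))
        fn = int(np.sum((preds != cls) & (truth == cls)))
        degenerate = False
        if tp + fp == 0:
            precision, degenerate = 0.0, True
        else:
            precision = tp / (tp + fp)
        if tp + fn == 0:
            recall, degenerate = 0.0, True
        else:
            recall = tp / (tp + fn)
        if precision + recall == 0:
            f1, degenerate = 0.0, True
        else:
            f1 = 2 * precision * recall / (precision + recall)
        per_class[cls] = ClassReport(precision=precision, recall=recall,
                                     f1=f1, support=int(np.sum(truth == cls)),
                                     degenerate=degenerate)
        f1s.append(f1)
    accuracy = float(np.mean(preds == truth))
    return CVReport(per_class=per_class, accuracy=accuracy,
                    macro_f1=float(np.mean(f1s)),
                    fold_assignment=np.empty(0, dtype=int),
                    predictions=preds, truth=truth)


def cross_validate(features: FeatureTable, config: ClassifierConfig,
                   smote_mode: str = "paper") -> CVReport:
    """10-fold CV of the SMOTE-balanced linear SVM.

    ``smote_mode="paper"``: balance the whole table, then split — the
    published ordering (train/test partitions of ~1978/220 at
    316 + 1099 trials), which leaks synthetic test-derived points into
    training.  ``smote_mode="leakfree"``: split the original trials,
    then oversample within each training fold only, so no synthetic row
    is derived from a held-out trial (guaranteed by construction: the
    SMOTE input is the training rows alone).
    """
    if smote_mode not in ("paper", "leakfree"):
        raise ValueError("smote_mode must be 'paper' or 'leakfree'")
    cfg = config
    if smote_mode == "paper":
        table, synth = balance_with_smote(features, k=cfg.k_smote,
                                          seed=cfg.seed)
        folds = kfold_split(len(table.y), cfg.n_folds, seed=cfg.seed)
        preds = np.empty(len(table.y), dtype=table.y.dtype)
        train_sizes, test_sizes = [], []
        for f in range(cfg.n_folds):
            test = folds == f
            preds[test] = fit_predict_svm(table.X[~test], table.y[~test],
                                          table.X[test], cfg)
            train_sizes.append(int((~test).sum()))
            test_sizes.append(int(test.sum()))
        report = evaluate(preds, table.y)
        report.synthetic_mask = synth
    else:
        folds = kfold_split(len(features.y), cfg.n_folds, seed=cfg.seed)
        preds = np.empty(len(features.y), dtype=features.y.dtype)
        train_sizes, test_sizes = [], []
        for f in range(cfg.n_folds):
            test = folds == f
            tr_X, tr_y = features.X[~test], features.y[~test]
            n_min = int(np.sum(tr_y == MINORITY))
            n_maj = int(np.sum(tr_y == MAJORITY))
            if n_maj > n_min:
                rows, _ = smote_oversample(tr_X[tr_y == MINORITY],
                                           n_maj - n_min, k=cfg.k_smote,
                                           seed=cfg.seed + f)
                tr_X = np.vstack([tr_X, rows])
                tr_y = np.concatenate([tr_y, np.full(len(rows), MINORITY)])
            preds[test] = fit_predict_svm(tr_X, tr_y, features.X[test], cfg)
            train_sizes.append(len(tr_y))
            test_sizes.append(int(test.sum()))
        report = evaluate(preds, features.y)
        report.synthetic_mask = np.zeros(len(features.y), bool)
    report.fold_assignment = folds
    report.fold_train_sizes = train_sizes
    report.fold_test_sizes = test_sizes
    return report


def permutation_significance(features: FeatureTable, config: ClassifierConfig,
                             n_perm: int | None = None,
                             smote_mode: str = "paper") -> tuple[float, float]:
    """Label-permutation p-value for the CV accuracy.

    Returns ``(observed accuracy, p)`` with
    ``p = (1 + #{perm accuracy >= observed}) / (1 + n_perm)``.
    """
    n_perm = config.n_perm if n_perm is None else n_perm
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = cross_validate(features, config, smote_mode).accuracy
    rng = np.random.default_rng(config.seed)
    hits = 0
    for _ in range(n_perm):
        shuffled = FeatureTable(features.X, rng.permutation(features.y),
                                features.feature_names)
        acc = cross_validate(shuffled, config, smote_mode).accuracy
        hits += acc >= observed
    return observed, (1 + hits) / (1 + n_perm)


def compare_models(preds_a: np.ndarray, preds_b: np.ndarray,
                   truth: np.ndarray) -> tuple[float, float]:
    """Paired t-test on per-trial correctness of two models.

    Correctness is the 0/1 indicator against the shared truth on the
    same held-out trials; a zero-variance difference returns (0, 1).
    The sign is (model A correct rate) minus (model B correct rate).
    """
    preds_a, preds_b = np.asarray(preds_a), np.asarray(preds_b)
    truth = np.asarray(truth)
    if not (len(preds_a) == len(preds_b) == len(truth)):
        raise ValueError("prediction vectors must align with the truth")
    ca = (preds_a == truth).astype(float)
    cb = (preds_b == truth).astype(float)
    diff = ca - cb
    if np.allclose(diff.std(ddof=1) if len(diff) > 1 else 0.0, 0.0):
        return 0.0, 1.0
    t, p = stats.ttest_rel(ca, cb)
    return float(t), float(p)
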