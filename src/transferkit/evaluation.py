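"""Leave-one-subject-out cross-validation with class rebalancing.

Each subject's rows are held out in turn, measuring generalization to unseen
users. Standardization is fitted on training rows only (no leakage into the
held-out subject). Accuracy is averaged unweighted across subjects (one vote
per subject) and a global 2x2 confusion matrix is accumulated over folds.

For the severely imbalanced detection task, the majority class is randomly
undersampled per subject to a 1:1 ratio before cross-validation; minority
rows are never touched or duplicated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score as _sk_f1
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError
from .featurematrix import FeatureMatrix

CLASSIFIER_FAMILIES = ("svm", "random_forest", "naive_bayes", "mlr")
_ALIASES = {"rf": "random_forest", "nb": "naive_bayes"}

#: defaults used when the task gives no hyperparameters; all overridable
DEFAULT_CONFIG = {
    "svm_kernel": "linear",
    "svm_c": 1.0,
    "rf_trees": 100,
    "mlr_l2_strength": 1e-4,
}


def make_classifier(family: str, seed: int = 0, config: dict | None = None):
    """Instantiate one of the four classifier families with fixed defaults."""
    family = _ALIASES.get(family, family)
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    if family == "svm":
        return SVC(kernel=cfg["svm_kernel"], C=cfg["svm_c"], random_state=seed)
    if family == "random_forest":
        return RandomForestClassifier(n_estimators=cfg["rf_trees"], random_state=seed)
    if family == "naive_bayes":
        return GaussianNB()
    if family == "mlr":
        return LogisticRegression(C=1.0 / cfg["mlr_l2_strength"], max_iter=5000)
    raise ConfigError(f"unknown classifier family {family!r}")


class MemorizingClassifier:
    """Harness self-test oracle: memorizes training rows, predicts by lookup."""

    def fit(self, X, y):
        self._table = {np.asarray(row, float).tobytes(): lab for row, lab in zip(X, y)}
        return self

    def predict(self, X):
        return np.asarray([self._table[np.asarray(r, float).tobytes()] for r in X])


def loso_folds(fm: FeatureMatrix) -> Iterator[tuple[np.ndarray, np.ndarray, str]]:
    """Yield (train_idx, test_idx, subject) with one fold per subject."""
    subjects = sorted({str(g) for g in fm.groups})
    if len(subjects) < 2:
        raise ConfigError("LOSO requires >= 2 subjects")
    groups = np.asarray([str(g) for g in fm.groups])
    for s in subjects:
        test = np.where(groups == s)[0]
        train = np.where(groups != s)[0]
        yield train, test, s


def rebalance(fm: FeatureMatrix, seed: int) -> FeatureMatrix:
    """Per-subject 1:1 random undersampling of the majority class.

    Deterministic under a fixed seed; minority rows are kept untouched and
    no row is ever duplicated. Row order is preserved.
    """
    fm.require_two_classes()
    rng = np.random.default_rng(seed)
    groups = np.asarray([str(g) for g in fm.groups])
    labels = np.asarray([str(l) for l in fm.labels])
    classes = fm.class_order()
    keep: list[int] = []
    for s in sorted(set(groups)):
        rows = np.where(groups == s)[0]
        by_class = {c: rows[labels[rows] == c] for c in classes}
        missing = [c for c, r in by_class.items() if len(r) == 0]
        if missing:
            raise ConfigError(f"subject {s} has no rows of class {missing[0]!r}")
        n_min = min(len(r) for r in by_class.values())
        for c in classes:
            r = by_class[c]
            if len(r) > n_min:
                r = rng.choice(r, size=n_min, replace=False)
            keep.extend(int(i) for i in r)
    return fm.take_rows(sorted(keep))


@dataclass
class CVResult:
    """Per-subject and global metrics of one LOSO run."""

    classifier: str
    per_subject: dict[str, tuple[float, float]]  # subject -> (accuracy, weighted F1)
    mean_accuracy: float
    sd_accuracy: float
    confusion: np.ndarray  # 2x2 counts, rows = actual, cols = predicted
    class_order: list[str]
    seed: int
    skipped_folds: list[str] = field(default_factory=list)

    def row_percentages(self) -> np.ndarray:
        sums = self.confusion.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(sums > 0, 100.0 * self.confusion / sums, 0.0)
        return pct


def run_cv(
    fm: FeatureMatrix,
    classifier: str = "svm",
    seed: int = 0,
    config: dict | None = None,
    feature_selector=None,
) -> CVResult:
    """LOSO cross-validation of one classifier family over the matrix.

    Per fold, features are z-scored with statistics fitted on the training
    rows only; the model is then fitted and scored on the held-out subject.
    ``feature_selector``, if given, is called on the training matrix of each
    fold and must return a list of feature names to use for that fold
    (per-fold selection mode).
    """
    fm.require_two_classes()
    family = _ALIASES.get(classifier, classifier)
    if family not in CLASSIFIER_FAMILIES:
        raise ConfigError(f"unknown classifier family {classifier!r}")
    classes = fm.class_order()
    labels = np.asarray([str(l) for l in fm.labels])
    per_subject: dict[str, tuple[float, float]] = {}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    skipped: list[str] = []
    for train, test, subject in loso_folds(fm):
        y_train = labels[train]
        if len(set(y_train)) < 2:
            warnings.warn(f"fold {subject}: single-class training set, skipped")
            skipped.append(subject)
            continue
        X_train, X_test = fm.X[train], fm.X[test]
        if feature_selector is not None:
            names = feature_selector(fm.take_rows(train))
            idx = [fm.feature_names.index(n) for n in names]
            X_train, X_test = X_train[:, idx], X_test[:, idx]
        scaler = StandardScaler().fit(X_train)
        clf = make_classifier(family, seed=seed, config=config)
        clf.fit(scaler.transform(X_train), y_train)
        y_pred = clf.predict(scaler.transform(X_test))
        y_true = labels[test]
        acc = float(np.mean(y_pred == y_true))
        f1 = float(_sk_f1(y_true, y_pred, average="weighted", zero_division=0))
        per_subject[subject] = (acc, f1)
        confusion += _sk_confusion(y_true, y_pred, labels=classes)
    if not per_subject:
        raise ConfigError("all folds were degenerate; nothing evaluated")
    accs = np.asarray([a for a, _ in per_subject.values()])
    return CVResult(
        classifier=family,
        per_subject=per_subject,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        confusion=confusion,
        class_order=classes,
        seed=seed,
        skipped_folds=skipped,
    )


def resubstitution_accuracy(fm: FeatureMatrix, clf=None) -> float:
    """Train and test on the same rows (harness sanity mode)."""
    clf = clf if clf is not None else MemorizingClassifier()
    labels = np.asarray([str(l) for l in fm.labels])
    clf.fit(fm.X, labels)
    return float(np.mean(clf.predict(fm.X) == labels))


def summarize(result: CVResult) -> str:
    """Render the per-subject table, global confusion matrix and mean (SD) line."""
    lines = [f"classifier: {result.classifier}"]
    lines.append("subject  accuracy  weighted_F1")
    for s, (acc, f1) in sorted(result.per_subject.items()):
        lines.append(f"{s:>7}  {100 * acc:7.1f}%  {f1:11.3f}")
    lines.append(
        f"mean accuracy {100 * result.mean_accuracy:.1f}% "
        f"(SD {100 * result.sd_accuracy:.1f}%)"
    )
    pct = result.row_percentages()
    lines.append("confusion (actual x predicted, counts and row %):")
    header = "  ".join(f"{c:>18}" for c in result.class_order)
    lines.append(f"{'':>12}{header}")
    for i, c in enumerate(result.class_order):
        cells = "  ".join(
            f"{result.confusion[i, j]:>8} ({pct[i, j]:5.1f}%)"
            for j in range(len(result.class_order))
        )
        lines.append(f"{c:>12}  {cells}")
    if result.skipped_folds:
        lines.append(f"skipped folds: {', '.join(result.skipped_folds)}")
    return "\n".join(lines)
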