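"""AAA severity classification from the reconstructed abdominal-aorta
pressure cycle.

A 1-D CNN grades the cycle into healthy / small / medium / large.
Training uses stratified 10-fold cross-validation inside the 80 %
training split (class proportions preserved per fold), then refits on
the full training split; the 20 % test split is only touched for the
final evaluation.  In the end-to-end pipeline the classifier consumes
the inverse model's predicted distal abdominal-aorta cycle, not the
simulator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .aneurysm import SeverityClass
from .nn import ConvClassifier, softmax
from .nn.conv import categorical_cross_entropy

CLASS_NAMES = tuple(c.value for c in SeverityClass)


@dataclass
class ClassifierConfig:
    """CNN hyperparameters; defaults are the full-scale settings and
    ``desk()`` the reduced schedule for small cohorts."""

    filters: tuple[int, ...] = (128, 128, 256, 256)
    kernel_size: int = 10
    dense_units: tuple[int, ...] = (16, 8)
    n_classes: int = 4
    n_folds: int = 10
    epochs: int = 100
    cv_epochs: int | None = None     # defaults to `epochs`
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    @classmethod
    def desk(cls, seed: int = 0) -> "ClassifierConfig":
        return cls(epochs=120, cv_epochs=30, batch_size=8,
                   learning_rate=3e-3, seed=seed)


class StratificationError(ValueError):
    """A class has fewer members than the number of folds."""


def build_classifier(config: ClassifierConfig,
                     input_len: int) -> ConvClassifier:
    return ConvClassifier(
        n_classes=config.n_classes, input_len=input_len,
        kernel=config.kernel_size, filters=config.filters,
        dense=config.dense_units, seed=config.seed)


def stratified_folds(labels: np.ndarray, n_folds: int, seed: int):
    """Stratified fold indices: each index held out exactly once and
    class proportions preserved per fold (within one patient)."""
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=1)
    low = [int(c) for c in counts if 0 < c < n_folds]
    if low:
        raise StratificationError(
            f"stratified {n_folds}-fold needs >= {n_folds} members per "
            f"class; smallest class has {min(low)}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


@dataclass
class Normalizer1D:
    mean: float
    std: float

    @classmethod
    def fit(cls, X):
        s = float(np.std(X))
        return cls(mean=float(np.mean(X)), std=s if s > 1e-12 else 1.0)

    def __call__(self, X):
        return (X - self.mean) / self.std


@dataclass
class TrainedClassifier:
    model: ConvClassifier
    config: ClassifierConfig
    norm: Normalizer1D
    fold_accuracies: list[float] = field(default_factory=list)

    @property
    def cv_accuracy_pct(self) -> float:
        return 100.0 * float(np.mean(self.fold_accuracies))

    def predict(self, X_mmhg: np.ndarray) -> np.ndarray:
        return self.model.predict(self.norm(X_mmhg))


def train_classifier_cv(X_mmhg: np.ndarray, labels: np.ndarray,
                        config: ClassifierConfig,
                        verbose: bool = False) -> TrainedClassifier:
    """Stratified K-fold cross-validation, then refit on all rows.

    ``X_mmhg``: (n, N) abdominal-aorta pressure cycles (the training
    split of the study); returns per-fold held-out accuracies and the
    refit model.
    """
    X = np.asarray(X_mmhg, dtype=float)
    labels = np.asarray(labels, dtype=int)
    norm = Normalizer1D.fit(X)
    Xn = norm(X)
    folds = stratified_folds(labels, config.n_folds, config.seed)
    cv_epochs = config.cv_epochs or config.epochs
    fold_acc = []
    for k, (fit_idx, val_idx) in enumerate(folds):
        m = build_classifier(config, X.shape[1])
        m.fit(Xn[fit_idx], labels[fit_idx], epochs=cv_epochs,
              batch_size=config.batch_size, lr=config.learning_rate,
              seed=config.seed + 100 + k)
        acc = float(np.mean(m.predict(Xn[val_idx]) == labels[val_idx]))
        fold_acc.append(acc)
        if verbose:
            print(f"  fold {k + 1}/{len(folds)}: accuracy {acc:.2%}")
    model = build_classifier(config, X.shape[1])
    model.fit(Xn, labels, epochs=config.epochs,
              batch_size=config.batch_size, lr=config.learning_rate,
              seed=config.seed + 7)
    return TrainedClassifier(model=model, config=config, norm=norm,
                             fold_accuracies=fold_acc)


def evaluate_classifier(trained: TrainedClassifier, X_mmhg: np.ndarray,
                        labels: np.ndarray):
    """Confusion matrix plus severity and detection accuracies.

    Severity accuracy is trace/total over the 4x4 confusion matrix;
    detection accuracy collapses classes to healthy vs any-AAA, so only
    AAA cases predicted healthy count as false negatives.
    """
    labels = np.asarray(labels, dtype=int)
    pred = trained.predict(X_mmhg)
    C = trained.config.n_classes
    confusion = np.zeros((C, C), dtype=int)
    for t, p in zip(labels, pred):
        confusion[t, p] += 1
    n = len(labels)
    severity_acc = float(np.trace(confusion)) / n if n else float("nan")
    detect_correct = np.sum((labels > 0) == (pred > 0))
    detection_acc = float(detect_correct) / n if n else float("nan")
    return confusion, 100.0 * severity_acc, 100.0 * detection_acc
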