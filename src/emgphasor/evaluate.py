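"""Intra-subject five-fold leave-one-trial-out evaluation of LDA/SVM models."""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .features_classic import FeatureMatrix

log = logging.getLogger(__name__)


@dataclass
class EvalConfig:
    classifier: str = "svm_rbf"  # "lda_diag" | "svm_rbf"
    gamma_rule: str = "inverse_scale"  # "paper_product" | "inverse_scale"
    n_folds: int = 5
    z_score: bool = True
    svm_c: float = 1.0
    shuffle_folds: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in ("lda_diag", "svm_rbf"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.gamma_rule not in ("paper_product", "inverse_scale"):
            raise ValueError(f"unknown gamma rule {self.gamma_rule!r}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class EvalResult:
    fold_acc: list[float]
    fold_mcc: list[float]
    acc_mean: float
    acc_std: float
    mcc_mean: float
    mcc_std: float
    confusion: np.ndarray  # (K, K) counts pooled over folds, rows = truth
    test_time_ms: list[float]
    subject_id: int = -1
    feature_set_name: str = ""
    classifier: str = ""
    gamma_rule: str | None = None
    skipped_folds: list[int] = field(default_factory=list)


def loto_folds(
    trial_ids: np.ndarray,
    n_folds: int = 5,
    seed: int | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition distinct trials into fold groups; each fold tests one group.

    Grouping follows sorted trial order (deterministic) unless a seed is
    given, in which case the trial order is shuffled once before splitting.
    Returns ``(train_trials, test_trials)`` pairs.
    """
    unique = np.unique(np.asarray(trial_ids))
    if unique.size < n_folds:
        raise ValueError(f"{unique.size} trials cannot fill {n_folds} folds")
    order = unique.copy()
    if seed is not None:
        np.random.default_rng(seed).shuffle(order)
    groups = np.array_split(order, n_folds)
    folds = []
    for g in groups:
        test = np.sort(g)
        train = np.sort(np.setdiff1d(unique, g))
        folds.append((train, test))
    return folds


def zscore_fit_apply(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score both matrices using statistics of the training rows only.

    Columns with zero training standard deviation are mapped to zero in both
    outputs.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training rows to fit a z-score")
    mean = train.mean(axis=0)
    std = train.std(axis=0, ddof=0)
    dead = std <= 0
    safe = np.where(dead, 1.0, std)
    zt = (train - mean) / safe
    zs = (test - mean) / safe
    zt[:, dead] = 0.0
    zs[:, dead] = 0.0
    return zt, zs


def svm_gamma(train: np.ndarray, rule: str = "inverse_scale") -> float:
    """RBF gamma from feature count and the flattened-matrix variance.

    ``paper_product`` multiplies the two; ``inverse_scale`` (default) is the
    reciprocal, matching the common 'scale' heuristic.
    """
    train = np.asarray(train, dtype=float)
    d = train.shape[1]
    var = float(train.var())
    if var <= 0:
        raise ValueError("training features have zero variance")
    if rule == "paper_product":
        return d * var
    if rule == "inverse_scale":
        return 1.0 / (d * var)
    raise ValueError(f"unknown gamma rule {rule!r}")


def accuracy(confusion: np.ndarray) -> float:
    """trace / total of a confusion matrix."""
    confusion = np.asarray(confusion, dtype=float)
    total = confusion.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(confusion) / total)


def mcc_multiclass(confusion: np.ndarray) -> float:
    """Multiclass Matthews correlation coefficient (Gorodkin's R_K).

    Returns 0 (with a warning) when the denominator vanishes, e.g. when all
    predictions or all truths collapse onto a single class.
    """
    c = np.asarray(confusion, dtype=float)
    if c.sum() <= 0:
        raise ValueError("empty confusion matrix")
    t = c.sum(axis=1)  # truths per class
    p = c.sum(axis=0)  # predictions per class
    s = c.sum()
    correct = np.trace(c)
    num = correct * s - float(t @ p)
    den = np.sqrt((s**2 - float(p @ p)) * (s**2 - float(t @ t)))
    if den == 0:
        warnings.warn("MCC denominator is zero; returning 0", RuntimeWarning, stacklevel=2)
        return 0.0
    return float(num / den)


class DiagonalLda:
    """Gaussian classifier with a shared (pooled) diagonal covariance.

    Per-class means, pooled per-feature variances and empirical priors; the
    discriminant is the diagonal-Mahalanobis distance plus the log prior.
    """

    def fit(self, x: np.ndarray, y: np.ndarray) -> "DiagonalLda":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        self.means_ = np.stack([x[y == c].mean(axis=0) for c in self.classes_])
        centered = x - self.means_[np.searchsorted(self.classes_, y)]
        self.var_ = np.maximum(centered.var(axis=0, ddof=0), 1e-12)
        self.log_priors_ = np.log(
            np.array([(y == c).mean() for c in self.classes_])
        )
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        # (n, K) negative half squared Mahalanobis distances under diag cov
        d2 = ((x[:, None, :] - self.means_[None]) ** 2 / self.var_).sum(axis=2)
        scores = -0.5 * d2 + self.log_priors_
        return self.classes_[np.argmax(scores, axis=1)]


def _make_classifier(cfg: EvalConfig, train: np.ndarray):
    if cfg.classifier == "lda_diag":
        return DiagonalLda(), None
    gamma = svm_gamma(train, cfg.gamma_rule)
    return SVC(kernel="rbf", C=cfg.svm_c, gamma=gamma, random_state=cfg.seed), gamma


def run_subject_eval(features: FeatureMatrix, cfg: EvalConfig) -> EvalResult:
    """Five-fold leave-one-trial-out fit/predict over one subject's features.

    Folds whose training split misses a class are skipped with a warning.
    Reported timing covers the test phase (normalization of test rows plus
    prediction) and is informational only.
    """
    folds = loto_folds(
        features.trial_ids,
        n_folds=cfg.n_folds,
        seed=cfg.seed if cfg.shuffle_folds else None,
    )
    classes = np.unique(features.labels)
    k = classes.size
    class_pos = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((k, k), dtype=int)
    fold_acc, fold_mcc, times, skipped = [], [], [], []

    for fold_i, (train_trials, test_trials) in enumerate(folds):
        tr = np.isin(features.trial_ids, train_trials)
        te = np.isin(features.trial_ids, test_trials)
        x_tr, y_tr = features.values[tr], features.labels[tr]
        x_te, y_te = features.values[te], features.labels[te]
        if np.unique(y_tr).size < 2 or np.unique(y_tr).size < k:
            log.warning("fold %d: training split misses a class; skipped", fold_i)
            skipped.append(fold_i)
            continue
        if cfg.z_score:
            x_tr, x_te = zscore_fit_apply(x_tr, x_te)
        clf, _ = _make_classifier(cfg, x_tr)
        clf.fit(x_tr, y_tr)
        t0 = time.perf_counter()
        y_hat = clf.predict(x_te)
        times.append((time.perf_counter() - t0) * 1000.0)
        fold_conf = np.zeros((k, k), dtype=int)
        for truth, pred in zip(y_te, y_hat):
            fold_conf[class_pos[truth], class_pos[pred]] += 1
        confusion += fold_conf
        fold_acc.append(accuracy(fold_conf))
        fold_mcc.append(mcc_multiclass(fold_conf))

    if not fold_acc:
        raise ValueError("every fold was skipped; cannot evaluate")
    return EvalResult(
        fold_acc=fold_acc,
        fold_mcc=fold_mcc,
        acc_mean=float(np.mean(fold_acc)),
        acc_std=float(np.std(fold_acc)),
        mcc_mean=float(np.mean(fold_mcc)),
        mcc_std=float(np.std(fold_mcc)),
        confusion=confusion,
        test_time_ms=times,
        subject_id=features.subject_id,
        feature_set_name=features.name,
        classifier=cfg.classifier,
        gamma_rule=cfg.gamma_rule if cfg.classifier == "svm_rbf" else None,
        skipped_folds=skipped,
    )
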