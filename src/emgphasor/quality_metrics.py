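"""Feature-space quality metrics: separability index and mean semi-principal axis."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

EPS = 1e-12
#: relative ridge added to pooled covariances before inversion
COV_RIDGE = 1e-9


def _class_split(features: np.ndarray, labels: np.ndarray) -> dict[int, np.ndarray]:
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.ndim != 2:
        raise ValueError("features must be (n_samples, D)")
    if labels.shape != (features.shape[0],):
        raise ValueError("labels must have one entry per sample")
    return {int(c): features[labels == c] for c in np.unique(labels)}


def _regularized(cov: np.ndarray) -> np.ndarray:
    cov = np.atleast_2d(cov)
    d = cov.shape[0]
    return cov + COV_RIDGE * (np.trace(cov) / d + EPS) * np.eye(d)


def _half_mahalanobis(xa: np.ndarray, xb: np.ndarray) -> float:
    """sqrt(0.5 * (ma-mb)^T Sigma^-1 (ma-mb)) with Sigma the pooled-pair covariance."""
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    sigma = _regularized((np.atleast_2d(np.cov(xa.T)) + np.atleast_2d(np.cov(xb.T))) / 2.0)
    try:
        delta = np.linalg.solve(sigma, np.atleast_1d(ma - mb))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"pooled covariance is singular even after ridge regularization: {err}"
        ) from err
    return float(np.sqrt(max(0.5 * float((ma - mb) @ delta), 0.0)))


def pairwise_class_distances(features: np.ndarray, labels: np.ndarray) -> dict[tuple[int, int], float]:
    """Half-Mahalanobis distance for every unordered class pair."""
    groups = _class_split(features, labels)
    classes = sorted(groups)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c, x in groups.items():
        if x.shape[0] < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
    out = {}
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            out[(a, b)] = _half_mahalanobis(groups[a], groups[b])
    return out


def most_conflicting(features: np.ndarray, labels: np.ndarray, class_i: int) -> int:
    """Class whose centroid is nearest to ``class_i`` under the pair metric."""
    dists = pairwise_class_distances(features, labels)
    best, best_d = None, np.inf
    for (a, b), d in dists.items():
        if class_i not in (a, b):
            continue
        other = b if a == class_i else a
        if d < best_d:
            best, best_d = other, d
    if best is None:
        raise ValueError(f"class {class_i} not present in labels")
    return int(best)


def separability_index(features: np.ndarray, labels: np.ndarray) -> float:
    """Mean over classes of the distance to each class's most-conflicting class."""
    dists = pairwise_class_distances(features, labels)
    classes = sorted(set(np.asarray(labels, dtype=int)))
    total = 0.0
    for c in classes:
        total += min(d for pair, d in dists.items() if c in pair)
    return total / len(classes)


def mean_semi_principal_axis(features: np.ndarray, labels: np.ndarray) -> float:
    """Average geometric-mean semi-axis of each class's hyper-ellipsoid.

    Each class is centred and decomposed by SVD; singular values are scaled by
    ``1/sqrt(n_i - 1)`` so each semi-axis estimates a per-direction standard
    deviation (sample-size independent).  Directions with no variance are
    floored at a tiny epsilon inside the geometric mean.
    """
    groups = _class_split(features, labels)
    d = features.shape[1]
    axes_means = []
    for c, x in sorted(groups.items()):
        if x.shape[0] < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
        centered = x - x.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False) / np.sqrt(x.shape[0] - 1)
        semi_axes = np.zeros(d)
        semi_axes[: sv.size] = sv
        if np.any(semi_axes < EPS):
            log.warning("class %s has near-zero variance directions; MSA eps-floored", c)
        geo = float(np.exp(np.mean(np.log(np.maximum(semi_axes, EPS)))))
        axes_means.append(geo)
    return float(np.mean(axes_means))


@dataclass
class QualityReport:
    """Per-subject, per-feature-set quality summary."""

    si: float
    msa: float
    per_class_conflict: dict[int, int]
    K: int
    D: int
    subject_id: int = -1
    feature_set_name: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.si) and self.si >= 0):
            raise ValueError("SI must be finite and non-negative")
        if not (np.isfinite(self.msa) and self.msa >= 0):
            raise ValueError("MSA must be finite and non-negative")
        if self.K < 2:
            raise ValueError("need at least 2 classes")
        if len(self.per_class_conflict) != self.K:
            raise ValueError("conflict map must cover every class")


def quality_report(
    features: np.ndarray,
    labels: np.ndarray,
    subject_id: int = -1,
    feature_set_name: str = "",
) -> QualityReport:
    """Compute SI, MSA and the conflict map for one feature space.

    Metrics are intended to run on unnormalized features (normalization
    happens later, only for classification).
    """
    dists = pairwise_class_distances(features, labels)
    classes = sorted(set(np.asarray(labels, dtype=int)))
    conflict = {}
    for c in classes:
        candidates = {(a, b): d for (a, b), d in dists.items() if c in (a, b)}
        (a, b), _ = min(candidates.items(), key=lambda kv: kv[1])
        conflict[c] = b if a == c else a
    si = float(np.mean([min(d for p, d in dists.items() if c in p) for c in classes]))
    msa = mean_semi_principal_axis(features, labels)
    return QualityReport(
        si=si,
        msa=msa,
        per_class_conflict=conflict,
        K=len(classes),
        D=features.shape[1],
        subject_id=subject_id,
        feature_set_name=feature_set_name,
    )
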