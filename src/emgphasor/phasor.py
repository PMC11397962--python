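"""Phasor spatial-synergy embedding of per-channel EMG features.

Channel ``k`` of an ``N``-channel montage is assigned the complex direction
``exp(j*k*2*pi/N)``.  A per-channel feature vector then becomes a set of
phasors whose pairwise difference moduli capture the spatial contrast between
channels.  The generalized feature set concatenates the log of those moduli
with the log-ratio against the same construction on the time-differentiated
signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .features_classic import EPS, FeatureMatrix, rms, wl
from .preprocess import WindowSet

#: base features usable inside the phasor construction
BASE_FEATURES: dict[str, Callable[[np.ndarray], np.ndarray]] = {"WL": wl, "RMS": rms}


@dataclass(frozen=True)
class PhasorLayout:
    """Angular channel layout: channel k sits at angle ``k*2*pi/N``."""

    n_channels: int

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("phasor layout needs at least 2 channels")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_channels) * 2.0 * np.pi / self.n_channels

    @property
    def pair_index(self) -> list[tuple[int, int]]:
        """Lexicographically ordered unordered channel pairs (k < l)."""
        n = self.n_channels
        return [(k, l) for k in range(n) for l in range(k + 1, n)]

    @property
    def n_pairs(self) -> int:
        return self.n_channels * (self.n_channels - 1) // 2


def phasor_embed(f_values: np.ndarray, layout: PhasorLayout) -> np.ndarray:
    """Map per-channel feature values onto the complex unit directions."""
    f_values = np.asarray(f_values, dtype=float)
    if f_values.shape[-1] != layout.n_channels:
        raise ValueError(
            f"expected {layout.n_channels} channel values, got {f_values.shape[-1]}"
        )
    return f_values * np.exp(1j * layout.angles)


def pairwise_moduli(f_values: np.ndarray, layout: PhasorLayout) -> np.ndarray:
    """Moduli of pairwise phasor differences, in lexicographic pair order.

    Uses the trigonometric closed form
    ``sqrt(fk^2 + fl^2 - 2*fk*fl*cos((k-l)*2*pi/N))``, which is algebraically
    identical to ``|fk e^{j k 2pi/N} - fl e^{j l 2pi/N}|``.  Accepts a single
    length-N vector or a stack ``(..., N)`` and returns ``(..., N(N-1)/2)``.
    """
    f_values = np.asarray(f_values, dtype=float)
    n = layout.n_channels
    if f_values.shape[-1] != n:
        raise ValueError(f"expected {n} channel values, got {f_values.shape[-1]}")
    pairs = layout.pair_index
    k = np.array([p[0] for p in pairs])
    l = np.array([p[1] for p in pairs])
    cos_d = np.cos((k - l) * 2.0 * np.pi / n)
    fk = f_values[..., k]
    fl = f_values[..., l]
    sq = fk**2 + fl**2 - 2.0 * fk * fl * cos_d
    return np.sqrt(np.maximum(sq, 0.0))


def _base_feature_fn(base_feature: str) -> Callable[[np.ndarray], np.ndarray]:
    try:
        return BASE_FEATURES[base_feature.upper()]
    except KeyError:
        raise ValueError(
            f"unknown base feature {base_feature!r}; choose from {sorted(BASE_FEATURES)}"
        ) from None


def feature_moduli(win: WindowSet, base_feature: str = "WL") -> np.ndarray:
    """Df matrix: pairwise phasor moduli of the base feature per window."""
    fn = _base_feature_fn(base_feature)
    layout = PhasorLayout(win.n_channels)
    return pairwise_moduli(fn(win.windows), layout)


def gradient_features(win: WindowSet, base_feature: str = "WL") -> np.ndarray:
    """Df matrix computed on the first-differenced window signals.

    Differentiation is the plain first difference within each window (length
    L-1, no sampling-interval scaling): the log-ratio downstream cancels any
    constant time-scale factor.
    """
    fn = _base_feature_fn(base_feature)
    layout = PhasorLayout(win.n_channels)
    return pairwise_moduli(fn(np.diff(win.windows, axis=-1)), layout)


@dataclass
class PhasorFeatures:
    """Df, gradient Df and the assembled log/log-ratio feature block."""

    Df: np.ndarray  # (n_windows, n_pairs), >= 0
    grad_Df: np.ndarray  # same shape
    fphasor: np.ndarray  # (n_windows, 2 * n_pairs)
    pair_names: list[str]

    def __post_init__(self) -> None:
        if self.Df.shape != self.grad_Df.shape:
            raise ValueError("Df and grad_Df must share a shape")
        if self.fphasor.shape != (self.Df.shape[0], 2 * self.Df.shape[1]):
            raise ValueError("fphasor must have twice the Df columns")
        if np.any(self.Df < 0) or np.any(self.grad_Df < 0):
            raise ValueError("pairwise moduli must be non-negative")
        if not np.all(np.isfinite(self.fphasor)):
            raise ValueError("fphasor contains non-finite values")


def fphasor_set(win: WindowSet, base_feature: str = "WL", eps: float = EPS) -> PhasorFeatures:
    """Generalized phasor set: ``[log(Df), log(Df / grad_Df)]`` per window.

    Both log arguments receive an additive ``eps`` so silent channels stay
    finite.  For N channels the block has ``N*(N-1)`` columns.
    """
    layout = PhasorLayout(win.n_channels)
    Df = feature_moduli(win, base_feature)
    gDf = gradient_features(win, base_feature)
    log_d = np.log(Df + eps)
    log_r = np.log((Df + eps) / (gDf + eps))
    prefix = f"{base_feature.upper()}PH"
    pair_names = [f"{prefix}|d({k},{l})" for k, l in layout.pair_index]
    pair_names += [f"{prefix}|r({k},{l})" for k, l in layout.pair_index]
    return PhasorFeatures(
        Df=Df,
        grad_Df=gDf,
        fphasor=np.hstack([log_d, log_r]),
        pair_names=pair_names,
    )


def fphasor_feature_matrix(
    win: WindowSet, base_feature: str = "WL", eps: float = EPS
) -> FeatureMatrix:
    """:func:`fphasor_set` wrapped as a named FeatureMatrix."""
    pf = fphasor_set(win, base_feature, eps=eps)
    return FeatureMatrix(
        values=pf.fphasor,
        feature_names=pf.pair_names,
        labels=win.labels.copy(),
        trial_ids=win.trial_ids.copy(),
        subject_id=win.subject_id,
        name=f"{base_feature.upper()}-PHASOR",
    )


def phasor_combined_set(win: WindowSet, eps: float = EPS) -> FeatureMatrix:
    """Column-concatenation of the WL- and RMS-based phasor sets."""
    wl_fm = fphasor_feature_matrix(win, "WL", eps=eps)
    rms_fm = fphasor_feature_matrix(win, "RMS", eps=eps)
    return FeatureMatrix.hstack([wl_fm, rms_fm], name="PHASOR")
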