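"""Per-window scalar EMG features and the classic comparator feature sets.

All scalar primitives accept arrays of windows and operate over the trailing
(time) axis, so a whole :class:`~emgphasor.preprocess.WindowSet` is reduced in
one vectorised call.  The set builders return a :class:`FeatureMatrix` whose
column names encode ``SET|channel|descriptor``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.regression.linear_model import burg

from .preprocess import WindowSet

#: guard added inside logs/divisions to keep silent channels finite
EPS = 1e-12


@dataclass
class FeatureMatrix:
    """Windows-by-features matrix with labels and trial provenance."""

    values: np.ndarray  # (n_windows, D)
    feature_names: list[str]
    labels: np.ndarray
    trial_ids: np.ndarray
    subject_id: int
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, d = self.values.shape
        if len(self.feature_names) != d:
            raise ValueError("one name per feature column required")
        if len(set(self.feature_names)) != d:
            raise ValueError("feature names must be unique")
        self.labels = np.asarray(self.labels, dtype=int)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.labels.shape != (n,) or self.trial_ids.shape != (n,):
            raise ValueError("labels/trial_ids must have one entry per row")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @staticmethod
    def hstack(parts: list["FeatureMatrix"], name: str = "") -> "FeatureMatrix":
        """Column-concatenate feature sets computed on the same windows."""
        first = parts[0]
        for p in parts[1:]:
            if p.n_windows != first.n_windows:
                raise ValueError("row counts differ")
            if not np.array_equal(p.labels, first.labels):
                raise ValueError("label vectors differ")
        return FeatureMatrix(
            values=np.hstack([p.values for p in parts]),
            feature_names=[n for p in parts for n in p.feature_names],
            labels=first.labels.copy(),
            trial_ids=first.trial_ids.copy(),
            subject_id=first.subject_id,
            name=name or "+".join(p.name for p in parts),
        )


# ---------------------------------------------------------------------------
# scalar primitives (trailing axis = time)
# ---------------------------------------------------------------------------

def wl(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Waveform length: sum of absolute first differences."""
    x = np.asarray(x, dtype=float)
    if x.shape[axis] < 2:
        raise ValueError("waveform length requires at least 2 samples")
    return np.sum(np.abs(np.diff(x, axis=axis)), axis=axis)


def rms(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Root mean square of the samples."""
    x = np.asarray(x, dtype=float)
    if x.shape[axis] < 1:
        raise ValueError("rms requires at least 1 sample")
    return np.sqrt(np.mean(np.square(x), axis=axis))


def mav(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Mean absolute value."""
    x = np.asarray(x, dtype=float)
    if x.shape[axis] < 1:
        raise ValueError("mav requires at least 1 sample")
    return np.mean(np.abs(x), axis=axis)


def iemg(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Integrated EMG: sum of absolute values."""
    return np.sum(np.abs(np.asarray(x, dtype=float)), axis=axis)


def variance(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Sample variance with the n-1 denominator (zero-mean convention kept)."""
    x = np.asarray(x, dtype=float)
    L = x.shape[axis]
    if L < 2:
        raise ValueError("variance requires at least 2 samples")
    return np.sum(np.square(x), axis=axis) / (L - 1)


def zero_crossings(x: np.ndarray, threshold: float = 0.0, axis: int = -1) -> np.ndarray:
    """Count sign changes whose amplitude step exceeds the deadband threshold."""
    x = np.moveaxis(np.asarray(x, dtype=float), axis, -1)
    a, b = x[..., :-1], x[..., 1:]
    return np.sum((a * b < 0) & (np.abs(a - b) >= threshold), axis=-1)


def slope_sign_changes(x: np.ndarray, threshold: float = 0.0, axis: int = -1) -> np.ndarray:
    """Count local extrema (slope sign flips) above the deadband threshold."""
    x = np.moveaxis(np.asarray(x, dtype=float), axis, -1)
    d1 = x[..., 1:-1] - x[..., :-2]
    d2 = x[..., 1:-1] - x[..., 2:]
    keep = d1 * d2 > 0
    if threshold > 0:
        keep &= np.maximum(np.abs(d1), np.abs(d2)) >= threshold
    return np.sum(keep, axis=-1)


def wamp(x: np.ndarray, threshold: np.ndarray | float, axis: int = -1) -> np.ndarray:
    """Willison amplitude: count of sample-to-sample jumps above threshold."""
    x = np.moveaxis(np.asarray(x, dtype=float), axis, -1)
    jumps = np.abs(np.diff(x, axis=-1))
    thr = np.asarray(threshold)[..., None] if np.ndim(threshold) else threshold
    return np.sum(jumps > thr, axis=-1)


# ---------------------------------------------------------------------------
# feature-set builders
# ---------------------------------------------------------------------------

def _assemble(
    win: WindowSet,
    blocks: dict[str, np.ndarray],
    set_name: str,
    channel_names: list[str] | None = None,
) -> FeatureMatrix:
    """Interleave per-channel descriptor blocks channel-major into a matrix."""
    names, cols = [], []
    chans = channel_names or [f"ch{c}" for c in range(win.n_channels)]
    for c, ch in enumerate(chans):
        for desc, block in blocks.items():
            names.append(f"{set_name}|{ch}|{desc}")
            cols.append(block[:, c])
    return FeatureMatrix(
        values=np.column_stack(cols),
        feature_names=names,
        labels=win.labels.copy(),
        trial_ids=win.trial_ids.copy(),
        subject_id=win.subject_id,
        name=set_name,
    )


def htd_set(win: WindowSet, threshold: float = 0.0) -> FeatureMatrix:
    """Hudgins time-domain set: MAV, ZC, SSC, WL per channel."""
    x = win.windows
    blocks = {
        "MAV": mav(x),
        "ZC": zero_crossings(x, threshold).astype(float),
        "SSC": slope_sign_changes(x, threshold).astype(float),
        "WL": wl(x),
    }
    return _assemble(win, blocks, "HTD")


def _tdpsd_blocks(x: np.ndarray) -> dict[str, np.ndarray]:
    # even spectral moments m0/m2/m4 estimated via time-domain derivatives,
    # compressed with the customary ^0.1/0.1 transform before the log features
    d1 = np.diff(x, axis=-1)
    d2 = np.diff(d1, axis=-1)
    m0 = np.sqrt(np.sum(x**2, axis=-1) + EPS) ** 0.1 / 0.1
    m2 = np.sqrt(np.sum(d1**2, axis=-1) + EPS) ** 0.1 / 0.1
    m4 = np.sqrt(np.sum(d2**2, axis=-1) + EPS) ** 0.1 / 0.1
    sparsity = m0 / (np.sqrt(np.abs((m0 - m2) * (m0 - m4))) + EPS)
    irregularity = m2 / (np.sqrt(m0 * m4) + EPS)
    wl_ratio = np.sum(np.abs(d1), axis=-1) / (np.sum(np.abs(d2), axis=-1) + EPS)
    return {
        "LM0": np.log(m0 + EPS),
        "LM0M2": np.log(np.abs(m0 - m2) + EPS),
        "LM0M4": np.log(np.abs(m0 - m4) + EPS),
        "SPARSI": np.log(sparsity + EPS),
        "IRF": np.log(irregularity + EPS),
        "WLR": np.log(wl_ratio + EPS),
    }


def tdpsd_set(win: WindowSet) -> FeatureMatrix:
    """Six time-domain power spectral descriptors per channel."""
    return _assemble(win, _tdpsd_blocks(win.windows), "TDPSD")


def ar_coefficients(x: np.ndarray, order: int = 4) -> np.ndarray:
    """Burg autoregressive coefficients for each (window, channel) series.

    Degenerate (constant) series yield all-zero coefficients rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    lead = x.shape[:-1]
    flat = x.reshape(-1, x.shape[-1])
    out = np.zeros((flat.shape[0], order))
    for i, series in enumerate(flat):
        if np.ptp(series) < EPS:
            continue
        coefs, _ = burg(series, order, demean=False)
        out[i] = np.nan_to_num(coefs, nan=0.0, posinf=0.0, neginf=0.0)
    return out.reshape(*lead, order)


def tdar_set(win: WindowSet, ar_order: int = 4, threshold: float = 0.0) -> FeatureMatrix:
    """Hudgins time-domain set augmented with Burg AR coefficients."""
    x = win.windows
    blocks = {
        "MAV": mav(x),
        "ZC": zero_crossings(x, threshold).astype(float),
        "SSC": slope_sign_changes(x, threshold).astype(float),
        "WL": wl(x),
    }
    ar = ar_coefficients(x, order=ar_order)  # (n, C, order)
    for p in range(ar_order):
        blocks[f"AR{p + 1}"] = ar[..., p]
    return _assemble(win, blocks, "TDAR")


def du_set(
    win: WindowSet,
    wamp_rms_fraction: float = 0.05,
    threshold: float = 0.0,
) -> FeatureMatrix:
    """Du feature set: IEMG, VAR, WAMP, ZC, SSC, WL per channel.

    The WAMP deadband adapts per window and channel to a fraction of that
    channel's RMS, so the count is scale-free.
    """
    x = win.windows
    blocks = {
        "IEMG": iemg(x),
        "VAR": variance(x),
        "WAMP": wamp(x, wamp_rms_fraction * rms(x)).astype(float),
        "ZC": zero_crossings(x, threshold).astype(float),
        "SSC": slope_sign_changes(x, threshold).astype(float),
        "WL": wl(x),
    }
    return _assemble(win, blocks, "Du")
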