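"""Band-pass filtering and labelled sliding-window segmentation."""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from ._filters import zero_lag_bandpass
from .synth_emg import EmgRecording

DEFAULT_WINDOW_MS = 150.0
DEFAULT_INCREMENT_MS = 25.0


def samples_from_ms(ms: float, fs: float) -> int:
    """Convert a duration in milliseconds to a sample count (round to nearest)."""
    return int(round(ms * fs / 1000.0))


@dataclass
class WindowSet:
    """Sliding analysis windows for one subject, with labels and provenance."""

    windows: np.ndarray  # (n_windows, n_channels, L)
    labels: np.ndarray  # (n_windows,)
    trial_ids: np.ndarray  # (n_windows,)
    subject_id: int
    fs: float
    window_ms: float = DEFAULT_WINDOW_MS
    increment_ms: float = DEFAULT_INCREMENT_MS

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.windows.ndim != 3:
            raise ValueError("windows must be (n_windows, n_channels, L)")
        n = self.windows.shape[0]
        if self.labels.shape != (n,) or self.trial_ids.shape != (n,):
            raise ValueError("labels and trial_ids must have one entry per window")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]

    @property
    def window_length(self) -> int:
        return self.windows.shape[2]

    @staticmethod
    def concat(parts: list["WindowSet"]) -> "WindowSet":
        """Stack window sets from several trials of the same subject."""
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if p.window_length != first.window_length or p.n_channels != first.n_channels:
                raise ValueError("incompatible window geometry")
            if p.subject_id != first.subject_id:
                raise ValueError("all windows must come from one subject")
        return WindowSet(
            windows=np.concatenate([p.windows for p in parts], axis=0),
            labels=np.concatenate([p.labels for p in parts]),
            trial_ids=np.concatenate([p.trial_ids for p in parts]),
            subject_id=first.subject_id,
            fs=first.fs,
            window_ms=first.window_ms,
            increment_ms=first.increment_ms,
        )


def bandpass_filter(
    rec: EmgRecording,
    low: float = 10.0,
    high: float = 400.0,
    order: int = 4,
) -> EmgRecording:
    """Zero-lag Butterworth band-pass each channel (forward-backward pass).

    The design order applies per pass; the forward-backward application makes
    the effective magnitude response the square of the single-pass response
    and the phase identically zero.  Labels and length are preserved.
    """
    filtered = zero_lag_bandpass(rec.samples, low, high, rec.fs, order=order, axis=1)
    return dc_replace(rec, samples=filtered, labels=rec.labels.copy())


def majority_label(window_labels: np.ndarray, n_classes: int | None = None) -> int:
    """Majority vote over per-sample labels; ties break toward the later phase."""
    window_labels = np.asarray(window_labels, dtype=int)
    counts = np.bincount(window_labels, minlength=(n_classes or window_labels.max() + 1))
    # argmax on the reversed counts prefers the highest label among ties
    return int(counts.size - 1 - np.argmax(counts[::-1]))


def make_windows(
    rec: EmgRecording,
    window_ms: float = DEFAULT_WINDOW_MS,
    increment_ms: float = DEFAULT_INCREMENT_MS,
) -> WindowSet:
    """Segment a recording into labelled sliding windows.

    Produces ``floor((T - L) / S) + 1`` windows with ``L`` and ``S`` derived
    from the millisecond parameters.  A recording shorter than one window
    yields an empty set rather than an error.  Each window is labelled by the
    majority phase of its samples.
    """
    L = samples_from_ms(window_ms, rec.fs)
    S = samples_from_ms(increment_ms, rec.fs)
    if L < 1 or S < 1:
        raise ValueError("window and increment must be at least one sample")
    T = rec.n_samples
    if T < L:
        empty = np.empty((0, rec.n_channels, L))
        return WindowSet(
            windows=empty,
            labels=np.empty(0, dtype=int),
            trial_ids=np.empty(0, dtype=int),
            subject_id=rec.subject_id,
            fs=rec.fs,
            window_ms=window_ms,
            increment_ms=increment_ms,
        )
    n_windows = (T - L) // S + 1
    starts = np.arange(n_windows) * S
    idx = starts[:, None] + np.arange(L)[None, :]
    windows = rec.samples[:, idx].transpose(1, 0, 2)  # (n_windows, C, L)
    n_classes = int(rec.labels.max()) + 1 if rec.labels.size else 1
    labels = np.array([majority_label(rec.labels[i], n_classes) for i in idx])
    return WindowSet(
        windows=windows,
        labels=labels,
        trial_ids=np.full(n_windows, rec.trial_id),
        subject_id=rec.subject_id,
        fs=rec.fs,
        window_ms=window_ms,
        increment_ms=increment_ms,
    )


def windows_from_recordings(
    recordings: list[EmgRecording],
    window_ms: float = DEFAULT_WINDOW_MS,
    increment_ms: float = DEFAULT_INCREMENT_MS,
    filter_band: tuple[float, float] | None = (10.0, 400.0),
    filter_order: int = 4,
) -> WindowSet:
    """Filter and window a list of same-subject trials into one WindowSet.

    Windows never cross trial boundaries.  Set ``filter_band=None`` to skip
    the band-pass stage.
    """
    parts = []
    for rec in recordings:
        if filter_band is not None:
            rec = bandpass_filter(rec, *filter_band, order=filter_order)
        ws = make_windows(rec, window_ms=window_ms, increment_ms=increment_ms)
        if ws.n_windows:
            parts.append(ws)
    return WindowSet.concat(parts)
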