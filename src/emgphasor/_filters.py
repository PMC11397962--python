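"""Shared zero-lag Butterworth band-pass used by the simulator and preprocessing.

One code path designs and applies the filter so that the synthetic carrier and
the preprocessing stage cannot drift apart numerically.
"""

from __future__ import annotations

import numpy as np
from scipy import signal


def bandpass_sos(low: float, high: float, fs: float, order: int = 4) -> np.ndarray:
    """Design a band-pass Butterworth filter in second-order sections.

    Parameters
    ----------
    low, high
        Pass-band edges in Hz.  Must satisfy ``0 < low < high < fs / 2``.
    fs
        Sampling rate in Hz.
    order
        Filter order of a single pass.

    Returns
    -------
    ndarray
        SOS coefficient array suitable for :func:`scipy.signal.sosfiltfilt`.
    """
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2; got low={low}, "
            f"high={high}, fs={fs}"
        )
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    return signal.butter(order, (low, high), btype="bandpass", fs=fs, output="sos")


def zero_lag_bandpass(
    x: np.ndarray,
    low: float,
    high: float,
    fs: float,
    order: int = 4,
    axis: int = -1,
) -> np.ndarray:
    """Apply the band-pass filter forward and backward (zero phase lag)."""
    sos = bandpass_sos(low, high, fs, order=order)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=axis)


def butter_bandpass_gain(f: np.ndarray, low: float, high: float, order: int = 4) -> np.ndarray:
    """Analytic magnitude response of a single-pass band-pass Butterworth.

    Built from the low-pass prototype via the standard band-pass frequency
    transform; useful as an independent oracle for attenuation checks.
    """
    f = np.asarray(f, dtype=float)
    w = 2.0 * np.pi * f
    wl, wh = 2.0 * np.pi * low, 2.0 * np.pi * high
    w0 = np.sqrt(wl * wh)
    bw = wh - wl
    with np.errstate(divide="ignore", invalid="ignore"):
        nu = (w**2 - w0**2) / (bw * w)
    return 1.0 / np.sqrt(1.0 + nu ** (2 * order))
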