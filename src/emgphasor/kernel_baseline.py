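"""Small random-convolutional-kernel comparator (Rocket / Mini-Rocket style).

A deliberately minimal 84-kernel transform used as a data-driven baseline for
the hand-crafted feature sets: random dilated kernels are convolved with the
(channel-summed) window signal and pooled into the proportion of positive
values (PPV) and the maximum activation.  Not a full reimplementation of the
published 10,000-kernel transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .features_classic import FeatureMatrix
from .preprocess import WindowSet

DEFAULT_N_KERNELS = 84
ROCKET_LENGTHS = (7, 9, 11)
MINI_LENGTH = 9


@dataclass(frozen=True)
class Kernel:
    weights: np.ndarray
    bias: float
    dilation: int
    padding: bool
    channels: np.ndarray  # channel subset whose responses are summed

    @property
    def span(self) -> int:
        """Receptive-field extent in samples."""
        return (len(self.weights) - 1) * self.dilation + 1


@dataclass
class KernelBank:
    mode: str  # "rocket" | "minirocket"
    kernels: list[Kernel]
    input_length: int
    n_channels: int
    seed: int

    @property
    def n_kernels(self) -> int:
        return len(self.kernels)


def _random_dilation(rng: np.random.Generator, klen: int, L: int) -> int:
    # exponential-scale draw keeping the receptive field inside the window
    max_exp = np.log2((L - 1) / (klen - 1))
    return int(2 ** rng.uniform(0.0, max_exp))


def _random_channels(rng: np.random.Generator, n_channels: int) -> np.ndarray:
    n_sel = int(2 ** rng.uniform(0.0, np.log2(n_channels))) if n_channels > 1 else 1
    n_sel = int(np.clip(n_sel, 1, n_channels))
    return np.sort(rng.choice(n_channels, size=n_sel, replace=False))


def build_bank(
    mode: str,
    L: int,
    n_channels: int,
    seed: int = 0,
    n_kernels: int = DEFAULT_N_KERNELS,
) -> KernelBank:
    """Build a deterministic random kernel bank.

    Rocket mode draws mean-centred Gaussian weights of length 7/9/11; the
    mini mode uses length-9 two-valued patterns (three weights of +2, six of
    -1), cycling through all 84 position combinations.  Both use uniform
    random bias in (-1, 1) and exponentially distributed dilations.
    """
    if mode not in ("rocket", "minirocket"):
        raise ValueError(f"mode must be 'rocket' or 'minirocket', got {mode!r}")
    if L < max(ROCKET_LENGTHS):
        raise ValueError(f"window length {L} too short for the kernel lengths")
    if n_kernels < 1:
        raise ValueError("n_kernels must be >= 1")
    mode_tag = {"rocket": 1, "minirocket": 2}[mode]
    rng = np.random.default_rng(np.random.SeedSequence((seed, mode_tag)))
    kernels = []
    mini_patterns = list(combinations(range(MINI_LENGTH), 3))  # 84 patterns
    for i in range(n_kernels):
        if mode == "rocket":
            klen = int(rng.choice(ROCKET_LENGTHS))
            w = rng.standard_normal(klen)
            w = w - w.mean()
        else:
            klen = MINI_LENGTH
            w = np.full(klen, -1.0)
            w[list(mini_patterns[i % len(mini_patterns)])] = 2.0
        kernels.append(
            Kernel(
                weights=w,
                bias=float(rng.uniform(-1.0, 1.0)),
                dilation=_random_dilation(rng, klen, L),
                padding=bool(rng.integers(0, 2)),
                channels=_random_channels(rng, n_channels),
            )
        )
    return KernelBank(mode=mode, kernels=kernels, input_length=L, n_channels=n_channels, seed=seed)


def apply_kernel(series: np.ndarray, kernel: Kernel) -> np.ndarray:
    """Dilated convolution of a batch of 1-D series ``(n, L)`` with one kernel."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    d = kernel.dilation
    if kernel.padding:
        pad = ((len(kernel.weights) - 1) // 2) * d
        series = np.pad(series, ((0, 0), (pad, pad)))
    n_out = series.shape[1] - (len(kernel.weights) - 1) * d
    if n_out < 1:
        raise ValueError("kernel receptive field exceeds the input length")
    out = np.full((series.shape[0], n_out), kernel.bias)
    for j, wj in enumerate(kernel.weights):
        out += wj * series[:, j * d : j * d + n_out]
    return out


def transform(win: WindowSet, bank: KernelBank, ppv_only: bool = False) -> FeatureMatrix:
    """Pool each kernel's activation map into PPV (and MAX) features.

    By default both statistics are emitted for both modes; ``ppv_only=True``
    restores the canonical Mini-Rocket behaviour of PPV pooling alone.
    """
    if win.window_length < max(k.span for k in bank.kernels) and not any(
        k.padding for k in bank.kernels
    ):
        raise ValueError("window length incompatible with the kernel bank")
    cols, names = [], []
    for i, kernel in enumerate(bank.kernels):
        summed = win.windows[:, kernel.channels, :].sum(axis=1)
        act = apply_kernel(summed, kernel)
        cols.append(np.mean(act > 0, axis=1))
        names.append(f"{bank.mode}|k{i}|PPV")
        if not ppv_only:
            cols.append(np.max(act, axis=1))
            names.append(f"{bank.mode}|k{i}|MAX")
    return FeatureMatrix(
        values=np.column_stack(cols),
        feature_names=names,
        labels=win.labels.copy(),
        trial_ids=win.trial_ids.copy(),
        subject_id=win.subject_id,
        name="Rocket" if bank.mode == "rocket" else "Mini-Rocket",
    )
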