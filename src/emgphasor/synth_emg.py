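"""Synthetic multichannel gait EMG with controllable spatial-synergy structure.

The generator produces band-limited Gaussian carriers whose per-channel
amplitude envelope is gated by the current gait phase through a
channel-by-phase gain matrix.  Phase durations are unbalanced and jittered
per cycle, envelope transitions are smoothed with a short raised-cosine
crossfade, and white sensor noise is added on top.  Everything is
deterministic given the config seed and the (subject, trial) indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from ._filters import zero_lag_bandpass

#: canonical five-phase gait labels
DEFAULT_PHASE_NAMES = ("HS", "FF", "MS", "HO", "TO")

#: unbalanced per-phase mean durations in ms, mimicking stance/swing asymmetry
DEFAULT_PHASE_DURATIONS_MS = (100.0, 150.0, 250.0, 200.0, 300.0)

#: raised-cosine crossfade length at phase transitions
CROSSFADE_MS = 10.0


def synergy_matrix(
    n_channels: int = 9,
    n_phases: int = 5,
    contrast: float = 3.0,
    base: float = 0.2,
    width: float = 1.2,
) -> np.ndarray:
    """Build a channel-by-phase gain matrix with tunable column contrast.

    Each phase preferentially activates a contiguous (circular) group of
    channels centred at ``p * n_channels / n_phases``; ``contrast`` scales the
    bump height above the ``base`` floor.  ``contrast == 0`` yields identical
    columns, i.e. no phase information in the envelope.
    """
    if contrast < 0 or base < 0:
        raise ValueError("contrast and base must be non-negative")
    c = np.arange(n_channels)[:, None]
    centers = np.arange(n_phases)[None, :] * n_channels / n_phases
    d = np.abs(c - centers)
    d = np.minimum(d, n_channels - d)  # circular channel distance
    return base + contrast * np.exp(-0.5 * (d / width) ** 2)


@dataclass
class SynthConfig:
    """Parameters of the synthetic gait EMG generator."""

    n_channels: int = 9
    n_phases: int = 5
    fs: float = 1920.0
    phase_durations_ms: Sequence[float] = DEFAULT_PHASE_DURATIONS_MS
    duration_jitter: float = 0.1
    synergy_gains: np.ndarray | None = None
    carrier_band: tuple[float, float] = (20.0, 350.0)
    noise_std: float = 0.05
    n_cycles: int = 2
    n_trials: int = 10
    subject_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.synergy_gains is None:
            self.synergy_gains = synergy_matrix(self.n_channels, self.n_phases)
        self.synergy_gains = np.asarray(self.synergy_gains, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.phase_durations_ms) != self.n_phases:
            raise ValueError("phase_durations_ms must have one entry per phase")
        if any(d <= 0 for d in self.phase_durations_ms):
            raise ValueError("phase durations must be positive")
        if not 0.0 <= self.duration_jitter < 1.0:
            raise ValueError("duration_jitter must be in [0, 1)")
        low, high = self.carrier_band
        if not 0.0 < low < high < self.fs / 2.0:
            raise ValueError("carrier_band must lie inside (0, fs/2)")
        if self.synergy_gains.shape != (self.n_channels, self.n_phases):
            raise ValueError(
                "synergy_gains must have shape (n_channels, n_phases); got "
                f"{self.synergy_gains.shape}"
            )
        if np.any(self.synergy_gains < 0):
            raise ValueError("synergy gains must be non-negative")
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")
        if self.n_cycles < 1 or self.n_trials < 1:
            raise ValueError("n_cycles and n_trials must be >= 1")


@dataclass
class EmgRecording:
    """One labelled multichannel EMG trial."""

    samples: np.ndarray  # (n_channels, n_samples)
    fs: float
    labels: np.ndarray  # (n_samples,) integer phase ids
    trial_id: int
    subject_id: int
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if self.labels.shape != (self.samples.shape[1],):
            raise ValueError("labels must align with the time dimension")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if not self.channel_names:
            self.channel_names = [f"ch{c}" for c in range(self.samples.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def _phase_labels(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-sample phase ids for ``cfg.n_cycles`` cycles with jittered durations."""
    chunks = []
    for _ in range(cfg.n_cycles):
        for p, base_ms in enumerate(cfg.phase_durations_ms):
            jitter = cfg.duration_jitter * (2.0 * rng.random() - 1.0)
            n = int(round(base_ms * (1.0 + jitter) * cfg.fs / 1000.0))
            chunks.append(np.full(max(n, 1), p, dtype=int))
    return np.concatenate(chunks)


def _envelope(cfg: SynthConfig, gains: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Piecewise-constant per-channel gain with raised-cosine crossfades."""
    env = gains[:, labels]  # (channels, time)
    m = int(round(CROSSFADE_MS * cfg.fs / 1000.0))
    if m > 1:
        kernel = np.hanning(m + 2)[1:-1]
        kernel /= kernel.sum()
        env = ndimage.convolve1d(env, kernel, axis=1, mode="nearest")
    return env


def generate_trial(
    cfg: SynthConfig,
    trial_id: int = 0,
    subject_id: int = 0,
    gains: np.ndarray | None = None,
) -> EmgRecording:
    """Generate one labelled synthetic trial.

    The per-channel signal is zero-mean band-limited Gaussian noise (unit RMS
    carrier) multiplied by the phase-gated envelope, plus white noise of
    standard deviation ``cfg.noise_std``.  Bit-identical output for identical
    ``(cfg, trial_id, subject_id)``.

    ``gains`` overrides ``cfg.synergy_gains`` (used for per-subject
    perturbations by :func:`generate_dataset`).
    """
    cfg.validate()
    if gains is None:
        gains = cfg.synergy_gains
    gains = np.asarray(gains, dtype=float)
    rng = np.random.default_rng(
        np.random.SeedSequence((int(cfg.seed), int(subject_id), int(trial_id)))
    )

    labels = _phase_labels(cfg, rng)
    n = labels.size

    carrier = rng.standard_normal((cfg.n_channels, n))
    carrier = zero_lag_bandpass(carrier, *cfg.carrier_band, cfg.fs, axis=1)
    scale = carrier.std(axis=1, keepdims=True)
    carrier = carrier / np.maximum(scale, 1e-30)

    samples = carrier * _envelope(cfg, gains, labels)
    if cfg.noise_std > 0:
        samples = samples + cfg.noise_std * rng.standard_normal(samples.shape)

    return EmgRecording(
        samples=samples,
        fs=cfg.fs,
        labels=labels,
        trial_id=int(trial_id),
        subject_id=int(subject_id),
    )


def subject_gains(cfg: SynthConfig, subject_id: int) -> np.ndarray:
    """Deterministic per-subject multiplicative log-normal gain perturbation."""
    rng = np.random.default_rng(
        np.random.SeedSequence((int(cfg.seed), 0x5EED, int(subject_id)))
    )
    if cfg.subject_sigma <= 0:
        return cfg.synergy_gains.copy()
    factor = rng.lognormal(mean=0.0, sigma=cfg.subject_sigma, size=cfg.synergy_gains.shape)
    return cfg.synergy_gains * factor


def generate_dataset(cfg: SynthConfig, n_subjects: int = 1) -> list[EmgRecording]:
    """Generate ``n_subjects * cfg.n_trials`` recordings.

    Subjects differ by a deterministic log-normal perturbation of the synergy
    gain matrix; trials within a subject differ only through the RNG stream.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    cfg.validate()
    recordings = []
    for s in range(n_subjects):
        g = subject_gains(cfg, s)
        for t in range(cfg.n_trials):
            recordings.append(generate_trial(cfg, trial_id=t, subject_id=s, gains=g))
    return recordings


def with_contrast(cfg: SynthConfig, contrast: float, base: float = 0.2) -> SynthConfig:
    """Copy of ``cfg`` with a freshly built gain matrix at the given contrast."""
    return replace(
        cfg,
        synergy_gains=synergy_matrix(cfg.n_channels, cfg.n_phases, contrast=contrast, base=base),
    )
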