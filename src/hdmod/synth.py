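"""Seeded synthetic 5-class, 64-channel EMG feature streams (and raw signals).

The generator emulates the structure of forearm surface-EMG gesture
recordings from a 16 x 4 electrode grid: four active gestures plus rest, in
3-second trials at 10 feature frames per second, ten trials per class.
Each active class owns a smooth random spatial activation template (a
Gaussian random field over the grid, so neighbouring electrodes co-activate
as they do under a shared muscle); every trial modulates the template with
an onset-hold-offset envelope and additive amplitude noise, clipped to
[0, 1].  The raw-signal generator drives a 20-150 Hz band-limited carrier
with the same envelope and adds 60 Hz mains pickup, so the preprocessing
chain can be exercised end to end.

It stands in for real recordings in all tests; what it deliberately does
not model is subject/session variability, electrode shift, or motor-unit
firing statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage, signal as sps

from hdmod.core import STREAM_DATA, STREAM_NOISE, derived_rng
from hdmod.ncc import GESTURE_CLASSES

__all__ = ["SyntheticConfig", "class_templates", "generate_features", "generate_raw"]

GRID_SHAPE = (16, 4)  # electrode grid geometry


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic feature generator.

    separability
        In (0, 1]; the weight of each class's *unique* activation field
        against a field common to all active classes (gestures share most
        of the forearm musculature, so their spatial patterns overlap).
        Pairwise template distances grow monotonically with it; 1 makes
        the active classes fully distinct.
    noise_sd
        Standard deviation of the additive per-frame amplitude noise.

    The defaults (separability 0.15, noise_sd 0.05) are calibrated once so
    that the noise-free classification pipeline at D = 10000 sits in the
    mid-90 % accuracy regime typical of real multichannel EMG, keeping
    robustness trends visible rather than saturated.
    """

    n_classes: int = 5
    n_channels: int = 64
    trial_seconds: float = 3.0
    trials_per_class: int = 10
    frame_rate: float = 10.0
    separability: float = 0.3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.separability <= 1.0:
            raise ValueError(f"separability must lie in (0, 1], got {self.separability}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if min(self.n_classes, self.n_channels, self.trials_per_class) < 1:
            raise ValueError("n_classes, n_channels and trials_per_class must be positive")
        if self.trial_seconds <= 0 or self.frame_rate <= 0:
            raise ValueError("trial_seconds and frame_rate must be positive")

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.trial_seconds * self.frame_rate))

    @property
    def n_trials(self) -> int:
        return self.n_classes * self.trials_per_class

    @property
    def n_frames(self) -> int:
        return self.n_trials * self.frames_per_trial


def class_templates(config: SyntheticConfig) -> np.ndarray:
    """Per-class spatial activation templates, shape (n_classes, n_channels).

    Class 0 (rest) is a small flat baseline.  Each active class mixes a
    smoothed Gaussian random field *common* to all gestures (the shared
    forearm musculature) with a class-unique field, weighted by
    ``separability``, then rescales the mix to [0.15, 0.9].  Templates
    depend only on ``config.seed``.
    """
    rng = derived_rng(config.seed, STREAM_DATA)
    use_grid = config.n_channels == GRID_SHAPE[0] * GRID_SHAPE[1]

    def smooth_field() -> np.ndarray:
        if use_grid:
            f = ndimage.gaussian_filter(rng.normal(size=GRID_SHAPE), sigma=1.5, mode="wrap")
            return f.ravel()
        return ndimage.gaussian_filter1d(rng.normal(size=config.n_channels), sigma=2.0, mode="wrap")

    common = smooth_field()
    templates = np.zeros((config.n_classes, config.n_channels))
    templates[0] = 0.02  # rest: near-silent baseline
    s = config.separability
    for c in range(1, config.n_classes):
        field = (1.0 - s) * common + s * smooth_field()
        lo, hi = field.min(), field.max()
        field = (field - lo) / (hi - lo) if hi > lo else np.zeros_like(field)
        templates[c] = 0.15 + 0.75 * field
    return templates


def _trial_envelope(frames_per_trial: int) -> np.ndarray:
    """Onset-hold-offset amplitude envelope (0.5 s ramps at the nominal rate).

    The low-amplitude ramp frames resemble rest, so decisions near trial
    boundaries are genuinely ambiguous -- the error mode transition frames
    exhibit in real gesture streams."""
    ramp = min(5, max(1, frames_per_trial // 4))
    up = np.linspace(0.0, 1.0, ramp + 1)[1:]
    down = up[::-1]
    hold = np.ones(max(frames_per_trial - 2 * ramp, 0))
    env = np.concatenate([up, hold, down])
    return env[:frames_per_trial]


def _trial_order(config: SyntheticConfig) -> np.ndarray:
    """Class label of each trial: runs cycling through all classes."""
    return np.tile(np.arange(config.n_classes), config.trials_per_class)


def generate_features(
    config: SyntheticConfig, noise_seed: Optional[int] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Generate a labelled feature stream.

    Returns ``(features, labels)`` with ``features`` of shape
    (n_frames, n_channels) in [0, 1] and one integer label per frame
    (0 = rest).  Templates are fixed by ``config.seed``; envelopes and
    noise draw from ``noise_seed`` (default: a stream derived from the
    config seed), so a train/test pair shares templates but not noise.
    """
    templates = class_templates(config)
    rng = derived_rng(config.seed if noise_seed is None else noise_seed, STREAM_NOISE)
    fpt = config.frames_per_trial
    env = _trial_envelope(fpt)
    order = _trial_order(config)
    features = np.empty((config.n_frames, config.n_channels))
    labels = np.empty(config.n_frames, dtype=np.int64)
    for t, cls in enumerate(order):
        block = env[:, None] * templates[cls][None, :]
        if config.noise_sd > 0:
            block = block + rng.normal(0.0, config.noise_sd, size=block.shape)
        features[t * fpt : (t + 1) * fpt] = block
        labels[t * fpt : (t + 1) * fpt] = cls
    np.clip(features, 0.0, 1.0, out=features)
    return features, labels


def generate_raw(
    config: SyntheticConfig,
    noise_seed: Optional[int] = None,
    fs: float = 1000.0,
    mains_amplitude: float = 0.2,
) -> Tuple[np.ndarray, np.ndarray]:
    """Generate raw 1 kS/s signals whose envelope follows the feature stream.

    Each channel is a 20-150 Hz band-limited Gaussian carrier amplitude-
    modulated by the (noise-free) feature envelope, plus a 60 Hz mains
    component.  Returns ``(raw, labels)`` with ``raw`` of shape
    (n_frames * fs / frame_rate, n_channels) and per-frame labels as in
    :func:`generate_features`.
    """
    noise_free = SyntheticConfig(
        n_classes=config.n_classes,
        n_channels=config.n_channels,
        trial_seconds=config.trial_seconds,
        trials_per_class=config.trials_per_class,
        frame_rate=config.frame_rate,
        separability=config.separability,
        noise_sd=0.0,
        seed=config.seed,
    )
    features, labels = generate_features(noise_free)
    rng = derived_rng(config.seed if noise_seed is None else noise_seed, STREAM_NOISE, 1)
    upsample = int(round(fs / config.frame_rate))
    env = np.repeat(features, upsample, axis=0)  # zero-order hold to sample rate
    n_samples = env.shape[0]
    sos = sps.butter(4, [20.0, 150.0], btype="bandpass", fs=fs, output="sos")
    carrier = sps.sosfilt(sos, rng.normal(size=(n_samples, config.n_channels)), axis=0)
    std = carrier.std(axis=0)
    std[std == 0] = 1.0
    carrier /= std
    t = np.arange(n_samples) / fs
    mains = mains_amplitude * np.sin(2 * np.pi * 60.0 * t)[:, None]
    raw = env * carrier + mains
    return raw, labels
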