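"""Near-channel classification and feature reconstruction for multichannel EMG.

The hybrid pipeline maps 64-channel surface-EMG feature frames (10 frames/s,
values nominally in [0, 1]) to hypervectors through one shared *spatial
encoder*: each channel's feature is quantized to L = 128 levels, embedded
with a distance-preserving continuous item memory (CiM), cyclically rotated
by the channel index, and superposed.  Two modes consume the same encoding:

- *classification*: five consecutive bipolarized spatial vectors are bound
  into a 5-gram under fixed random permutations, transmitted as a bipolar
  vector, and classified at the receiver by cosine similarity against
  per-class prototypes (an associative-memory search);
- *transmission*: the integer spatial vector is transmitted directly and the
  receiver reconstructs the 64 quantized features with an iterative
  interference-cancelling decoder over the CiM levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from hdmod.core import (
    STREAM_TIE_BREAKER,
    ContinuousItemMemory,
    PermutationSet,
    bipolarize,
    derived_rng,
    make_cim,
    random_bipolar,
    rotate,
)

__all__ = [
    "NccConfig",
    "NccEncoder",
    "ClassPrototypes",
    "emg_envelope",
    "fit_quantiles",
    "preprocess_emg",
    "quantize_features",
    "spatial_encode",
    "temporal_encode",
    "train_prototypes",
    "classify",
    "reconstruct_features",
    "reconstruct_stream",
    "emg_throughput",
    "mse_db",
]

GESTURE_CLASSES = ("rest", "fist", "raise", "lower", "open")


@dataclass(frozen=True)
class NccConfig:
    """Configuration of the hybrid encoder.

    The throughput of the encoding is (n_channels * log2(n_levels) *
    ngram_size) / dim -- 2240 / D for the default 64-channel, 128-level,
    5-gram layout -- so D below 2240 compresses the payload.
    """

    dim: int = 10000
    n_levels: int = 128
    n_channels: int = 64
    ngram_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ngram_size < 1:
            raise ValueError("ngram_size must be >= 1")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------


def emg_envelope(raw: np.ndarray, fs: float = 1000.0) -> np.ndarray:
    """Causal envelope chain on raw EMG sampled at ``fs`` (samples x channels).

    60 Hz notch (Q = 50), 8th-order Butterworth band-pass 1-200 Hz,
    rectification, 100-tap moving average, decimation by 100 (one frame per
    100 ms at the nominal 1 kS/s rate).  Output is *unnormalized*.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=np.float64))
    b, a = sps.iirnotch(60.0, 50.0, fs=fs)
    sos = sps.butter(4, [1.0, 200.0], btype="bandpass", fs=fs, output="sos")
    z = sps.lfilter(b, a, raw, axis=0)
    z = sps.sosfilt(sos, z, axis=0)
    z = np.abs(z)
    z = sps.lfilter(np.ones(100) / 100.0, [1.0], z, axis=0)
    return z[99::100]


def fit_quantiles(raw_train: np.ndarray, fs: float = 1000.0, p: float = 0.95) -> np.ndarray:
    """Per-channel normalization constants: the p-quantile of the training envelope."""
    return np.quantile(emg_envelope(raw_train, fs=fs), p, axis=0)


def preprocess_emg(raw: np.ndarray, quantiles: np.ndarray, fs: float = 1000.0) -> np.ndarray:
    """Raw EMG to feature frames: envelope chain, then per-channel quantile scaling.

    Features land in [0, 1] with high probability (the 95 % training
    quantile leaves ~5 % overshoot, clamped later at quantization).
    """
    if quantiles is None:
        raise ValueError("per-channel training quantiles are required for normalization")
    quantiles = np.asarray(quantiles, dtype=np.float64)
    if np.any(quantiles <= 0):
        raise ValueError("normalization quantiles must be positive")
    return emg_envelope(raw, fs=fs) / quantiles


def quantize_features(f: np.ndarray, n_levels: int = 128) -> np.ndarray:
    """Uniform quantizer on [0, 1]: level = clamp(floor(f * L) + 1, 1, L), 1-based."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    f = np.asarray(f, dtype=np.float64)
    return np.clip(np.floor(f * n_levels).astype(np.int64) + 1, 1, n_levels)


# ---------------------------------------------------------------------------
# spatial / temporal encoding
# ---------------------------------------------------------------------------


def spatial_encode(levels: np.ndarray, cim: ContinuousItemMemory) -> np.ndarray:
    """Superpose channel-rotated level vectors: x = sum_ch rotate(cim[level_ch], ch).

    ``levels`` holds 1-based quantization levels, last axis = channels.
    """
    levels = np.asarray(levels)
    n_ch = levels.shape[-1]
    d = cim.dim
    x = np.zeros(levels.shape[:-1] + (d,), dtype=np.int64)
    for ch in range(n_ch):
        x += rotate(cim.levels[levels[..., ch] - 1], ch)
    return x


def temporal_encode(
    frames: Sequence[np.ndarray],
    tie_breaker: np.ndarray,
    perms: PermutationSet,
) -> np.ndarray:
    """Bind ``n`` consecutive spatial vectors (chronological order) into an n-gram.

    Each frame is bipolarized; the newest frame enters unpermuted and the
    frame ``i`` steps back enters under the fixed random permutation
    ``perms[i]``.  The result is bipolar.
    """
    n = len(frames)
    if n < 1:
        raise ValueError("need at least one frame")
    if n > 1 and perms.n_perms < n - 1:
        raise ValueError(f"need {n - 1} permutations for an {n}-gram, set has {perms.n_perms}")
    out = bipolarize(np.asarray(frames[-1]), tie_breaker)
    for i in range(1, n):
        older = bipolarize(np.asarray(frames[-1 - i]), tie_breaker)
        out = out * perms.apply(older, i)
    return out.astype(np.int8)


@dataclass(frozen=True)
class ClassPrototypes:
    """One bipolar prototype vector per gesture class."""

    vectors: np.ndarray  # (n_classes, D) int8
    classes: Tuple[str, ...]

    @property
    def n_classes(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def train_prototypes(
    encoded: np.ndarray,
    labels: np.ndarray,
    tie_breaker: np.ndarray,
    classes: Optional[Sequence[str]] = None,
) -> ClassPrototypes:
    """Accumulate encoded training vectors per class and bipolarize the sums."""
    encoded = np.asarray(encoded)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if classes is None:
        classes = tuple(str(u) for u in uniq)
    protos = np.empty((len(uniq), encoded.shape[1]), dtype=np.int8)
    for i, u in enumerate(uniq):
        members = encoded[labels == u]
        if members.shape[0] == 0:
            raise ValueError(f"class {u!r} has no training samples")
        protos[i] = bipolarize(members.sum(axis=0, dtype=np.int64), tie_breaker)
    return ClassPrototypes(vectors=protos, classes=tuple(classes))


def classify(
    y: np.ndarray,
    prototypes: ClassPrototypes,
    bipolarize_query: bool = False,
) -> np.ndarray:
    """Nearest-prototype label(s) by cosine similarity; ties to the smallest index.

    With ``bipolarize_query`` the query is sign-thresholded first, making
    the search Hamming-equivalent (cheaper, but less accurate at low SNR).
    Accepts a single vector or a (batch, D) array.
    """
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    if bipolarize_query:
        y = np.where(y >= 0, 1.0, -1.0)
    norms = np.linalg.norm(y, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("cannot classify a zero query vector")
    scores = (y / norms) @ prototypes.vectors.T  # prototype norms are equal; argmax unaffected
    labels = np.argmax(scores, axis=1)
    return labels if labels.size > 1 else int(labels[0])


# ---------------------------------------------------------------------------
# feature reconstruction (transmission mode)
# ---------------------------------------------------------------------------


def reconstruct_stream(
    y: np.ndarray,
    cim: ContinuousItemMemory,
    feedback: str = "soft",
    max_iterations: int = 10,
    n_channels: int = 64,
) -> np.ndarray:
    """Reconstruct feature frames from (noisy) spatial superpositions.

    For every channel the receiver de-rotates the received vector and
    searches the L CiM levels (no rotation or sign search); with unit or
    soft feedback the other channels' re-encoded estimates are subtracted
    iteratively.  Estimated levels map back to bin centers (l - 0.5) / L.
    ``y`` is (frames, D) or (D,); returns matching (frames, n_channels).
    """
    if feedback not in ("none", "unit", "soft"):
        raise ValueError(f"feedback must be one of none/unit/soft, got {feedback!r}")
    y = np.asarray(y, dtype=np.float64)
    single = y.ndim == 1
    y = np.atleast_2d(y)
    n_frames, d = y.shape
    if d != cim.dim:
        raise ValueError(f"vector dim {d} does not match CiM dim {cim.dim}")
    lvl_mat = cim.levels.astype(np.float64)  # (L, D)
    ar = np.arange(d)
    derot_idx = (ar[None, :] + np.arange(n_channels)[:, None]) % d  # rotate(y, -ch)
    rot_idx = (ar[None, :] - np.arange(n_channels)[:, None]) % d  # rotate(e, +ch)

    y_derot = y[:, derot_idx]  # (F, ch, D)
    scores = y_derot @ lvl_mat.T / d  # (F, ch, L)
    est = np.argmax(scores, axis=2)
    conf = np.take_along_axis(scores, est[..., None], axis=2)[..., 0]

    if feedback != "none":
        active = np.ones(n_frames, dtype=bool)
        for _ in range(max_iterations - 1):
            if not np.any(active):
                break
            ea = est[active]  # (a, ch)
            entries = lvl_mat[ea]  # (a, ch, D)
            reenc = np.take_along_axis(entries, np.broadcast_to(rot_idx, entries.shape), axis=2)
            if feedback == "soft":
                reenc = reenc * np.clip(np.abs(conf[active]), 0.0, 1.0)[..., None]
            total = reenc.sum(axis=1)  # (a, D)
            cleaned = y[active][:, None, :] - total[:, None, :] + reenc  # (a, ch, D)
            cleaned = np.take_along_axis(cleaned, np.broadcast_to(derot_idx, cleaned.shape), axis=2)
            new_scores = cleaned @ lvl_mat.T / d
            new_est = np.argmax(new_scores, axis=2)
            conf[active] = np.take_along_axis(new_scores, new_est[..., None], axis=2)[..., 0]
            changed = np.any(new_est != ea, axis=1)
            est[active] = new_est
            idx_active = np.flatnonzero(active)
            active[idx_active[~changed]] = False

    values = (est + 0.5) / cim.n_levels  # 0-based est -> bin center (l - 0.5)/L
    return values[0] if single else values


def reconstruct_features(
    y: np.ndarray,
    cim: ContinuousItemMemory,
    feedback: str = "soft",
    max_iterations: int = 10,
    n_channels: int = 64,
) -> np.ndarray:
    """Reconstruct one frame's 64 features from a spatial superposition."""
    return reconstruct_stream(y, cim, feedback, max_iterations, n_channels)


def emg_throughput(dim: int) -> float:
    """Throughput of the 64-channel, 7-bit, 5-gram encoding: 2240 / D."""
    if dim <= 0:
        raise ValueError(f"dim must be positive, got {dim}")
    return 64 * 7 * 5 / dim


def mse_db(reconstructed: np.ndarray, original: np.ndarray) -> float:
    """Mean-squared error between feature arrays, in dB (-inf if identical)."""
    reconstructed = np.asarray(reconstructed, dtype=np.float64)
    original = np.asarray(original, dtype=np.float64)
    if reconstructed.shape != original.shape:
        raise ValueError(f"shape mismatch: {reconstructed.shape} vs {original.shape}")
    if reconstructed.size == 0:
        raise ValueError("cannot compute MSE of empty inputs")
    mse = float(np.mean((reconstructed - original) ** 2))
    return float(10.0 * np.log10(mse)) if mse > 0 else float("-inf")


# ---------------------------------------------------------------------------
# stateful encoder shared by both modes
# ---------------------------------------------------------------------------


class NccEncoder:
    """The spatial/temporal encoder shared by classification and transmission.

    Holds the CiM, the n-gram permutations and the bipolarization
    tie-breaker, all derived deterministically from ``config.seed``.
    """

    def __init__(self, config: NccConfig):
        self.config = config
        self.cim = make_cim(config.n_levels, config.dim, config.seed)
        n_perms = max(config.ngram_size - 1, 1)
        self.ngram_perms = PermutationSet.random(n_perms, config.dim, config.seed)
        self.tie_breaker = random_bipolar(config.dim, derived_rng(config.seed, STREAM_TIE_BREAKER))
        self._rot_cim: Optional[np.ndarray] = None

    def _rotated_cim(self) -> np.ndarray:
        # (n_channels, L, D) cache of channel-rotated level vectors
        if self._rot_cim is None:
            cfg = self.config
            d = cfg.dim
            cols = (np.arange(d)[None, :] - np.arange(cfg.n_channels)[:, None]) % d
            self._rot_cim = self.cim.levels[:, cols].transpose(1, 0, 2).copy()  # (ch, L, D)
        return self._rot_cim

    def spatial(self, features: np.ndarray) -> np.ndarray:
        """Quantize and spatially encode feature frames: (T, ch) -> (T, D) int."""
        cfg = self.config
        levels = quantize_features(features, cfg.n_levels)
        rc = self._rotated_cim()
        levels = np.atleast_2d(levels)
        x = np.zeros((levels.shape[0], cfg.dim), dtype=np.int64)
        for ch in range(cfg.n_channels):
            x += rc[ch, levels[:, ch] - 1]
        return x

    def ngrams(self, features: np.ndarray) -> np.ndarray:
        """Encode a feature stream into bipolar n-grams, one per frame from
        frame ``ngram_size - 1`` on: (T, ch) -> (T - n + 1, D) int8."""
        cfg = self.config
        x = self.spatial(features)
        b = bipolarize(x, self.tie_breaker)
        n = cfg.ngram_size
        t = b.shape[0]
        if t < n:
            raise ValueError(f"need at least {n} frames, got {t}")
        out = b[n - 1 :].astype(np.int8).copy()
        for i in range(1, n):
            out *= b[n - 1 - i : t - i][:, self.ngram_perms.perms[i - 1]]
        return out

    def encode_trials(
        self, features: np.ndarray, labels: np.ndarray, trial_len: int
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Encode a labelled stream trial by trial (n-grams never span trials).

        Returns (ngrams, ngram_labels); each trial of ``trial_len`` frames
        yields ``trial_len - ngram_size + 1`` decisions labelled with the
        trial's label.
        """
        features = np.asarray(features)
        labels = np.asarray(labels)
        n = self.config.ngram_size
        grams, glabels = [], []
        for lo in range(0, features.shape[0], trial_len):
            hi = min(lo + trial_len, features.shape[0])
            if hi - lo < n:
                continue
            grams.append(self.ngrams(features[lo:hi]))
            glabels.append(np.full(hi - lo - n + 1, labels[lo]))
        return np.concatenate(grams, axis=0), np.concatenate(glabels)

    def random_transmission(self, rng: np.random.Generator) -> np.ndarray:
        """A bipolar n-gram encoding ``ngram_size`` random feature frames.

        Used to model the payload of an unrelated interfering node (each
        node owns its encoder instance, hence its own dictionaries).
        """
        cfg = self.config
        feats = rng.random((cfg.ngram_size, cfg.n_channels))
        return self.ngrams(feats)[0]
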