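"""Channel models: AWGN with power-correct normalization, multi-node interference.

The received vector is y = x + n with n ~ N(0, (P/SNR) I_D), where P is the
per-dimension signal power: V for an integer superposition of V bipolar
vectors, 1 for a bipolar vector.  Interference from J unrelated nodes adds J
independently encoded, symbol-synchronous, equal-power bipolar vectors.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Union

import numpy as np

from hdmod.core import STREAM_INTERFERENCE, STREAM_NOISE, derived_rng, random_bipolar

__all__ = ["awgn", "ebn0_from_snr", "add_interference", "snr_linear"]

RngLike = Union[int, np.random.Generator]


def _as_rng(rng: Optional[RngLike], stream: int) -> np.random.Generator:
    if rng is None:
        return np.random.default_rng()
    if isinstance(rng, np.random.Generator):
        return rng
    return derived_rng(int(rng), stream)


def snr_linear(snr_db: float) -> float:
    """Convert an SNR in dB to the linear scale."""
    return float(10.0 ** (snr_db / 10.0))


def awgn(
    x: np.ndarray,
    snr_db: float,
    signal_power: float,
    rng: Optional[RngLike] = None,
) -> np.ndarray:
    """Add white Gaussian noise with per-dimension variance signal_power / SNR.

    ``snr_db = inf`` returns the input unchanged (noise-free flag).
    ``signal_power`` is the per-dimension power of the transmitted vector:
    V for an integer superposition of V bipolar vectors, 1 for a bipolar
    vector.  ``rng`` may be a Generator or an integer seed (a dedicated
    noise sub-stream is derived from it).
    """
    if signal_power <= 0:
        raise ValueError(f"signal_power must be positive, got {signal_power}")
    x = np.asarray(x, dtype=np.float64)
    if np.isinf(snr_db):
        return x.copy()
    gen = _as_rng(rng, STREAM_NOISE)
    sd = np.sqrt(signal_power / snr_linear(snr_db))
    return x + gen.normal(0.0, sd, size=x.shape)


def ebn0_from_snr(snr_db: float, r: float) -> float:
    """Energy per information bit over noise floor, E_b/N_0 := SNR / (2 r), in dB."""
    if r <= 0:
        raise ValueError(f"throughput r must be positive, got {r}")
    return float(snr_db - 10.0 * np.log10(2.0 * r))


def add_interference(
    x: np.ndarray,
    n_interferers: int,
    interferer_factory: Optional[Callable[[np.random.Generator], np.ndarray]] = None,
    rng: Optional[RngLike] = None,
) -> np.ndarray:
    """Superpose ``n_interferers`` equal-power, symbol-synchronous interferers.

    Each interferer is drawn by ``interferer_factory`` from its own derived
    stream -- in a system simulation this encodes a random payload through
    an *independent* node's dictionaries.  The default factory draws an
    i.i.d. bipolar vector, the marginal distribution of any independently
    encoded bipolar transmission.
    """
    if n_interferers < 0:
        raise ValueError(f"n_interferers must be >= 0, got {n_interferers}")
    x = np.asarray(x, dtype=np.float64)
    if n_interferers == 0:
        return x.copy()
    gen = _as_rng(rng, STREAM_INTERFERENCE)
    y = x.copy()
    for _ in range(n_interferers):
        node_rng = np.random.default_rng(gen.integers(0, 2**31))
        if interferer_factory is None:
            y += random_bipolar(x.shape[-1], node_rng)
        else:
            xi = np.asarray(interferer_factory(node_rng), dtype=np.float64)
            if xi.shape != x.shape:
                raise ValueError(f"interferer shape {xi.shape} does not match signal shape {x.shape}")
            y += xi
    return y
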