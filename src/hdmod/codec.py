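"""Integer hyperdimensional modulation: encoder and iterative feedback decoder.

A length-k binary string is split into V blocks of ``log2(N) + log2(D) + 1``
bits.  Each block selects a dictionary entry (q), a cyclic rotation (r) and a
sign (s); the block vector ``s * rho^r(e_q)`` is permuted with a block-unique
random permutation and all blocks are superposed into one integer vector of
dimension D.  The decoder alternates associative-memory searches over all
(q, r) pairs with interference cancellation: each block's query is the
received vector minus the re-encoded estimates of all other blocks, weighted
either at full scale (unit feedback) or by the previous estimate's
confidence clipped to one (soft feedback).  Fixed-point and readout
quantization model low-precision hardware decoders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence, Tuple

import numpy as np
import scipy.fft as _fft

from hdmod.core import (
    STREAM_TIE_BREAKER,
    ItemMemory,
    PermutationSet,
    derived_rng,
    make_item_memory,
    random_bipolar,
    rotate,
)

__all__ = [
    "CodeConfig",
    "BlockIndexes",
    "DecoderConfig",
    "DecodeResult",
    "bits_to_indexes",
    "indexes_to_bits",
    "encode",
    "throughput",
    "am_search",
    "decode",
    "Decoder",
    "quantize_readout",
    "quantize_fixed_point",
    "make_codebooks",
]

# Tolerance used to recognise exact ties of the search metric computed via
# floating-point transforms; inner products of integer vectors are exact
# multiples of 1/D, so anything closer than this is a true tie.
_TIE_ATOL = 1e-9


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class CodeConfig:
    """Integer-HDM code parameters.

    dim
        Vector dimension D (power of two, so the rotation index fills an
        integral number of bits).
    im_size
        Dictionary size N (power of two).
    n_superposed
        Number of superposed blocks V.
    seed
        Master seed; dictionary, permutations and the bipolarization
        tie-breaker are derived from independent sub-streams.
    """

    dim: int
    im_size: int
    n_superposed: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not _is_power_of_two(self.dim) or self.dim < 2:
            raise ValueError(f"dim must be a power of two >= 2, got {self.dim}")
        if not _is_power_of_two(self.im_size):
            raise ValueError(f"im_size must be a power of two, got {self.im_size}")
        if self.n_superposed < 1:
            raise ValueError(f"n_superposed must be >= 1, got {self.n_superposed}")

    @property
    def k_q(self) -> int:
        return int(np.log2(self.im_size))

    @property
    def k_r(self) -> int:
        return int(np.log2(self.dim))

    @property
    def k_s(self) -> int:
        return 1

    @property
    def block_bits(self) -> int:
        return self.k_q + self.k_r + self.k_s

    @property
    def n_bits(self) -> int:
        """Total information bits k = V * (log2 N + log2 D + 1)."""
        return self.n_superposed * self.block_bits


class BlockIndexes(NamedTuple):
    """Indexes of one encoded block: dictionary entry, rotation, sign."""

    q: int
    r: int
    s: int


@dataclass(frozen=True)
class DecoderConfig:
    """Iterative decoder settings.

    feedback
        'none' (single estimation pass), 'unit' (subtract estimates at full
        scale) or 'soft' (scale each subtracted estimate by the previous
        confidence, clipped to one).
    max_iterations
        Safety cap on decoding passes; convergence (all block indexes
        unchanged between consecutive passes) usually occurs after 2-3.
    readout_levels
        Optional V': quantize each block query to the symmetric step-two
        integer grid {-V', ..., V'} before the AM search.
    fixed_point
        Optional (m, q) bit widths: the received vector and the feedback
        scale are rounded to a fixed-point grid with m integer and q
        fractional bits.
    """

    feedback: str = "unit"
    max_iterations: int = 10
    readout_levels: Optional[int] = None
    fixed_point: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.feedback not in ("none", "unit", "soft"):
            raise ValueError(f"feedback must be one of none/unit/soft, got {self.feedback!r}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.readout_levels is not None and self.readout_levels < 1:
            raise ValueError("readout_levels must be >= 1")
        if self.fixed_point is not None:
            m, q = self.fixed_point
            if m < 1 or q < 0:
                raise ValueError(f"fixed_point widths must satisfy m >= 1, q >= 0, got {self.fixed_point}")


@dataclass(frozen=True)
class DecodeResult:
    """Decoder output: recovered bits, per-block indexes and diagnostics."""

    bits: str
    indexes: Tuple[BlockIndexes, ...]
    iterations: int
    converged: bool
    confidences: np.ndarray


def throughput(config: CodeConfig) -> float:
    """Code throughput r = V (log2 N + log2 D + 1) / D in bits per channel use."""
    return config.n_bits / config.dim


def _as_bits(u, expected_len: Optional[int] = None) -> np.ndarray:
    if isinstance(u, str):
        if set(u) - {"0", "1"}:
            raise ValueError("bit-string may contain only '0' and '1'")
        arr = np.frombuffer(u.encode(), dtype=np.uint8) - ord("0")
    else:
        arr = np.asarray(u, dtype=np.int64)
        if arr.ndim != 1 or np.any((arr != 0) & (arr != 1)):
            raise ValueError("bits must be a flat sequence of 0/1")
    if expected_len is not None and arr.size != expected_len:
        raise ValueError(f"expected {expected_len} bits, got {arr.size}")
    return arr.astype(np.int64)


def bits_to_indexes(u_block, config: CodeConfig) -> BlockIndexes:
    """Map one block's bit-string to (q, r, s).

    The block is sliced in order (q | r | s); each slice is read as an
    unsigned integer, most-significant bit first, and the single sign bit b
    maps to s = 2b - 1.
    """
    bits = _as_bits(u_block, config.block_bits)
    kq, kr = config.k_q, config.k_r
    q = int(bits[:kq] @ (1 << np.arange(kq - 1, -1, -1))) if kq else 0
    r = int(bits[kq : kq + kr] @ (1 << np.arange(kr - 1, -1, -1))) if kr else 0
    s = int(2 * bits[-1] - 1)
    return BlockIndexes(q=q, r=r, s=s)


def indexes_to_bits(idx: BlockIndexes, config: CodeConfig) -> str:
    """Exact inverse of :func:`bits_to_indexes`."""
    if not 0 <= idx.q < config.im_size:
        raise ValueError(f"q={idx.q} out of range 0..{config.im_size - 1}")
    if not 0 <= idx.r < config.dim:
        raise ValueError(f"r={idx.r} out of range 0..{config.dim - 1}")
    if idx.s not in (-1, 1):
        raise ValueError(f"s must be -1 or +1, got {idx.s}")
    qs = format(idx.q, f"0{config.k_q}b") if config.k_q else ""
    rs = format(idx.r, f"0{config.k_r}b") if config.k_r else ""
    ss = "1" if idx.s == 1 else "0"
    return qs + rs + ss


def make_codebooks(config: CodeConfig, identity_permutations: bool = False):
    """Instantiate the (item memory, permutation set, tie-breaker) for a config."""
    im = make_item_memory(config.im_size, config.dim, config.seed)
    if identity_permutations:
        perms = PermutationSet.identity(config.n_superposed, config.dim)
    else:
        perms = PermutationSet.random(config.n_superposed, config.dim, config.seed)
    tie = random_bipolar(config.dim, derived_rng(config.seed, STREAM_TIE_BREAKER))
    return im, perms, tie


def encode(u, im: ItemMemory, perms: PermutationSet, config: CodeConfig) -> np.ndarray:
    """Encode a k-bit string into the integer superposition x.

    x = sum_v Pi_v( s_v * rho^{r_v}( e_{q_v} ) ).
    """
    bits = _as_bits(u, config.n_bits)
    if im.n_items != config.im_size or im.dim != config.dim:
        raise ValueError("item memory shape does not match the code configuration")
    x = np.zeros(config.dim, dtype=np.int64)
    bb = config.block_bits
    for v in range(1, config.n_superposed + 1):
        idx = bits_to_indexes(bits[(v - 1) * bb : v * bb], config)
        block = idx.s * rotate(im.vectors[idx.q], idx.r)
        x += perms.apply(block, v)
    return x


def encode_indexes(indexes: Sequence[BlockIndexes], im: ItemMemory, perms: PermutationSet) -> np.ndarray:
    """Superpose already-mapped block indexes (the decoder's re-encoding path)."""
    x = np.zeros(im.dim, dtype=np.int64)
    for v, idx in enumerate(indexes, start=1):
        x += perms.apply(idx.s * rotate(im.vectors[idx.q], idx.r), v)
    return x


# ---------------------------------------------------------------------------
# associative-memory search over (q, r)
# ---------------------------------------------------------------------------


class _AMSearcher:
    """Batched search for the best (q, r, s) over all dictionary rotations.

    The metric c[q, r] = (1/D) <rho^{-r}(y), e_q> for all N*D pairs is a set
    of circular cross-correlations, evaluated either directly (exact
    reference) or via real FFTs (fast path).  Both paths resolve ties -- the
    metric takes values on a 1/D grid for integer queries -- by the
    lexicographically smallest (q, r), so they return identical indexes.
    """

    def __init__(self, im: ItemMemory, method: str = "fft", dtype=np.float64):
        if method not in ("fft", "direct"):
            raise ValueError(f"unknown search method {method!r}")
        self.im = im
        self.method = method
        self.dtype = dtype
        if method == "fft":
            e = im.vectors.astype(dtype)
            self._efft_conj = np.conj(_fft.rfft(e, axis=1))

    def correlations(self, y: np.ndarray) -> np.ndarray:
        """Return c with shape (..., N, D); c[..., q, r] per the search metric."""
        y = np.asarray(y)
        d = self.im.dim
        if y.shape[-1] != d:
            raise ValueError(f"query dim {y.shape[-1]} does not match dictionary dim {d}")
        if self.method == "direct":
            e = self.im.vectors.astype(np.float64)
            out = np.empty(y.shape[:-1] + (self.im.n_items, d))
            for r in range(d):
                out[..., :, r] = np.roll(y, -r, axis=-1) @ e.T / d
            return out
        yfft = _fft.rfft(y.astype(self.dtype), axis=-1)
        c = _fft.irfft(yfft[..., None, :] * self._efft_conj, n=d, axis=-1)
        c /= d
        return c

    def search(self, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Batched argmax of |c| with lexicographic (q, r) tie-breaking.

        Returns arrays (q, r, s, confidence) with ``y``'s batch shape.
        """
        c = self.correlations(y)
        d = self.im.dim
        a = np.abs(c).reshape(c.shape[:-2] + (-1,))
        peak = a.max(axis=-1, keepdims=True)
        # first index reaching the peak within tie tolerance, q-major order
        flat = np.argmax(a >= peak - _TIE_ATOL, axis=-1)
        q, r = np.divmod(flat, d)
        sel = np.take_along_axis(c.reshape(c.shape[:-2] + (-1,)), flat[..., None], axis=-1)[..., 0]
        s = np.where(sel < 0, -1, 1)
        return q, r, s, np.abs(sel)


def am_search(y_v: np.ndarray, im: ItemMemory, method: str = "fft") -> Tuple[BlockIndexes, float]:
    """Best-match search of a (inverse-permuted) block query over (q, r, sign).

    Returns the maximizing :class:`BlockIndexes` and the confidence
    ``|c[q, r]|`` (absolute normalized inner product of the winner).
    """
    searcher = _AMSearcher(im, method=method)
    q, r, s, conf = searcher.search(np.atleast_2d(np.asarray(y_v, dtype=np.float64)))
    return BlockIndexes(q=int(q[0]), r=int(r[0]), s=int(s[0])), float(conf[0])


# ---------------------------------------------------------------------------
# quantizers
# ---------------------------------------------------------------------------


def quantize_readout(y: np.ndarray, v_max: int) -> np.ndarray:
    """Map each element to the nearest value in {-V', -V'+2, ..., V'-2, V'}.

    The grid contains every value a noise-free superposition of V' bipolar
    vectors can take.  Halfway ties go to the smaller magnitude.
    """
    if v_max < 1:
        raise ValueError(f"v_max must be >= 1, got {v_max}")
    y = np.asarray(y, dtype=np.float64)
    lo = 2.0 * np.floor((y + v_max) / 2.0) - v_max
    lo = np.clip(lo, -v_max, v_max - 2 if v_max >= 2 else -v_max)
    hi = np.minimum(lo + 2.0, v_max)
    d_lo = np.abs(y - lo)
    d_hi = np.abs(hi - y)
    take_hi = (d_hi < d_lo) | ((d_hi == d_lo) & (np.abs(hi) < np.abs(lo)))
    # exact tie with equal magnitudes (y == 0 on an even grid): take the positive value
    take_hi |= (d_hi == d_lo) & (np.abs(hi) == np.abs(lo)) & (hi > 0)
    return np.where(take_hi, hi, lo)


def quantize_fixed_point(x: np.ndarray, m: int, q: int) -> np.ndarray:
    """Round to a fixed-point grid with m integer and q fractional bits.

    Step 2^-q, round-to-nearest with halfway ties away from zero, symmetric
    clipping to +/-(2^m - 2^-q).
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if q < 0:
        raise ValueError(f"q must be >= 0, got {q}")
    x = np.asarray(x, dtype=np.float64)
    step = 2.0 ** (-q)
    limit = 2.0**m - step
    y = np.sign(x) * np.floor(np.abs(x) / step + 0.5) * step
    return np.clip(y, -limit, limit)


# ---------------------------------------------------------------------------
# iterative feedback decoder
# ---------------------------------------------------------------------------


class Decoder:
    """Reusable iterative decoder for one (code, decoder) configuration.

    Precomputes the dictionary FFT once, so harnesses decoding many
    codewords avoid repeated setup.  ``method='direct'`` switches the AM
    search to the exact reference scan (for oracle comparisons).
    """

    def __init__(
        self,
        im: ItemMemory,
        perms: PermutationSet,
        config: CodeConfig,
        dconfig: DecoderConfig = DecoderConfig(),
        method: str = "fft",
        dtype=np.float64,
    ):
        if im.n_items != config.im_size or im.dim != config.dim:
            raise ValueError("item memory does not match the code configuration")
        if perms.n_perms < config.n_superposed or perms.dim != config.dim:
            raise ValueError("permutation set does not match the code configuration")
        self.im = im
        self.perms = perms
        self.config = config
        self.dconfig = dconfig
        self._searcher = _AMSearcher(im, method=method, dtype=dtype)
        v = config.n_superposed
        self._fwd = perms.perms[:v]
        self._inv = perms.inverse_perms[:v]

    def _reencode(self, q: np.ndarray, r: np.ndarray, s: np.ndarray) -> np.ndarray:
        """Vectorized re-encoding of V blocks: Pi_v(s_v rho^{r_v}(e_{q_v}))."""
        d = self.config.dim
        base = self.im.vectors[q]  # (V, D)
        cols = (np.arange(d)[None, :] - r[:, None]) % d  # rho^{r}: out[i] = e[(i - r) mod D]
        rot = np.take_along_axis(base, cols, axis=1)
        signed = rot * s[:, None]
        return np.take_along_axis(signed, self._fwd, axis=1)

    def decode(self, y: np.ndarray) -> DecodeResult:
        cfg, dcfg = self.config, self.dconfig
        v_count = cfg.n_superposed
        y = np.asarray(y, dtype=np.float64)
        if y.shape != (cfg.dim,):
            raise ValueError(f"expected a length-{cfg.dim} vector, got shape {y.shape}")
        if dcfg.fixed_point is not None:
            y = quantize_fixed_point(y, *dcfg.fixed_point)

        x_hat = np.zeros((v_count, cfg.dim))  # re-encoded block estimates
        scale = np.zeros(v_count)  # feedback weights of the previous pass
        prev = None
        conf = np.zeros(v_count)
        converged = False
        iterations = 0
        for _ in range(dcfg.max_iterations):
            iterations += 1
            cancelled = y - (scale[:, None] * x_hat).sum(axis=0)
            queries = cancelled[None, :] + scale[:, None] * x_hat  # leave each block's own signal in
            queries = np.take_along_axis(queries, self._inv, axis=1)
            if dcfg.readout_levels is not None:
                queries = quantize_readout(queries, dcfg.readout_levels)
            q, r, s, conf = self._searcher.search(queries)
            current = np.stack([q, r, s], axis=1)
            if prev is not None and np.array_equal(current, prev):
                converged = True
                break
            prev = current
            if dcfg.feedback == "none" or v_count == 1:
                # no interference to cancel (or cancellation disabled): one pass
                converged = True
                break
            x_hat = self._reencode(q, r, s).astype(np.float64)
            if dcfg.feedback == "soft":
                scale = np.minimum(conf, 1.0)
                if dcfg.fixed_point is not None:
                    scale = quantize_fixed_point(scale, *dcfg.fixed_point)
            else:
                scale = np.ones(v_count)

        indexes = tuple(BlockIndexes(int(qq), int(rr), int(ss)) for qq, rr, ss in prev)
        bits = "".join(indexes_to_bits(idx, cfg) for idx in indexes)
        return DecodeResult(
            bits=bits,
            indexes=indexes,
            iterations=iterations,
            converged=converged,
            confidences=np.asarray(conf, dtype=np.float64),
        )


def decode(
    y: np.ndarray,
    im: ItemMemory,
    perms: PermutationSet,
    config: CodeConfig,
    dconfig: DecoderConfig = DecoderConfig(),
    method: str = "fft",
) -> DecodeResult:
    """Decode a received vector with the iterative feedback decoder."""
    return Decoder(im, perms, config, dconfig, method=method).decode(y)
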