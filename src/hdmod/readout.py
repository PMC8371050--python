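"""Superposition retrieval: plain AM readout, learned MMSE readout, capacity.

These tools address the plain-superposition setting (no sign or rotation
encoding): V dictionary entries are permuted with block-unique permutations
and added, x = sum_v Pi_v(e_{q_v}).  Retrieval of the q_v from x uses either

- the *AM readout*: c_v = (1/D) E^T Pi_v^{-1}(x), argmax over N entries, or
- a *learned MMSE readout*: per-position matrices F_v minimizing the mean
  squared error between F_v^T x and the one-hot truth over a training set,
  which needs neither the dictionary nor the permutations at inference.

An iterative interference-cancelling wrapper (unit or soft feedback)
re-encodes the current estimates with the true dictionary and subtracts
them, exactly as the channel decoder does.  The operational capacity
statistic converts a retrieval probability into bits per dimension.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from hdmod.core import STREAM_DATA, ItemMemory, PermutationSet, derived_rng

__all__ = [
    "MMSEReadout",
    "RetrievalResult",
    "random_index_batch",
    "encode_superpositions",
    "train_mmse",
    "mmse_estimate",
    "am_estimate",
    "decode_iterative",
    "capacity",
]


@dataclass(frozen=True)
class MMSEReadout:
    """Per-position linear readout matrices F_v (each D x N).

    ``matrices`` has shape (V, D, N); position v estimates its symbol as
    ``argmax F_v^T x``.
    """

    matrices: np.ndarray
    n_train: int
    seed: int

    @property
    def n_positions(self) -> int:
        return self.matrices.shape[0]

    @property
    def dim(self) -> int:
        return self.matrices.shape[1]

    @property
    def n_symbols(self) -> int:
        return self.matrices.shape[2]


@dataclass(frozen=True)
class RetrievalResult:
    """Outcome of a retrieval experiment over a batch of superpositions."""

    estimates: np.ndarray  # (trials, V) estimated indexes
    accuracy: float  # fraction of positions retrieved correctly
    capacity_bits_per_dim: float
    mean_iterations: float


def random_index_batch(
    n_trials: int, n_positions: int, n_symbols: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random symbol indexes with shape (n_trials, n_positions)."""
    return rng.integers(0, n_symbols, size=(n_trials, n_positions))


def encode_superpositions(indexes: np.ndarray, im: ItemMemory, perms: PermutationSet) -> np.ndarray:
    """Encode index rows into plain permuted superpositions x = sum_v Pi_v(e_{q_v})."""
    indexes = np.asarray(indexes)
    n_trials, v_count = indexes.shape
    x = np.zeros((n_trials, im.dim), dtype=np.int64)
    for v in range(v_count):
        entry = im.vectors[indexes[:, v]]  # (trials, D)
        x += entry[:, perms.perms[v]]
    return x


def train_mmse(
    superpositions: np.ndarray,
    truths: np.ndarray,
    ridge: float = 1e-6,
    seed: int = 0,
) -> MMSEReadout:
    """Fit per-position MMSE readout matrices by least squares.

    ``superpositions`` is (R, D); ``truths`` is (R, V) integer symbol
    indexes.  The squared-error objective is convex, so the closed-form
    normal-equations solution coincides with converged (stochastic)
    gradient descent; a tiny ridge keeps the Gram matrix well posed.
    Training touches only the (x, c_v) pairs -- never the dictionary or the
    permutations.
    """
    x = np.asarray(superpositions, dtype=np.float64)
    t = np.asarray(truths)
    if x.ndim != 2 or t.ndim != 2 or x.shape[0] != t.shape[0]:
        raise ValueError(
            f"superpositions {x.shape} and truths {t.shape} must be paired (R, D) / (R, V)"
        )
    n_train, dim = x.shape
    v_count = t.shape[1]
    n_symbols = int(t.max()) + 1
    # one-hot targets for all positions at once: (R, V * N)
    c = np.zeros((n_train, v_count * n_symbols))
    rows = np.repeat(np.arange(n_train), v_count)
    cols = (np.arange(v_count) * n_symbols)[None, :] + t
    c[rows, cols.ravel()] = 1.0
    gram = x.T @ x + ridge * n_train * np.eye(dim)
    rhs = x.T @ c
    f = np.linalg.solve(gram, rhs)  # (D, V * N)
    matrices = np.transpose(f.reshape(dim, v_count, n_symbols), (1, 0, 2))
    return MMSEReadout(matrices=matrices, n_train=n_train, seed=seed)


def mmse_estimate(x: np.ndarray, readout: MMSEReadout, v: int) -> int:
    """Estimated symbol of position ``v`` (0-based): argmax of F_v^T x.

    Ties resolve to the smallest index (numpy argmax convention).
    """
    if not 0 <= v < readout.n_positions:
        raise ValueError(f"position v={v} out of range 0..{readout.n_positions - 1}")
    scores = np.asarray(x, dtype=np.float64) @ readout.matrices[v]
    return int(np.argmax(scores))


def am_estimate(x: np.ndarray, im: ItemMemory, perms: PermutationSet, v: int) -> int:
    """AM readout for position v: argmax of (1/D) E^T Pi_v^{-1}(x)."""
    scores = np.asarray(x, dtype=np.float64)[perms.inverse_perms[v]] @ im.matrix / im.dim
    return int(np.argmax(scores))


def _estimate_all(
    x: np.ndarray,
    im: Optional[ItemMemory],
    perms: Optional[PermutationSet],
    readout: Optional[MMSEReadout],
    v_count: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Estimate all positions of a batch; returns (indexes, confidences), each (trials, V)."""
    if readout is not None:
        scores = np.einsum("td,vdn->tvn", x, readout.matrices[:v_count], optimize=True)
    else:
        d = im.dim
        inv = np.stack([x[:, perms.inverse_perms[v]] for v in range(v_count)], axis=1)
        scores = inv @ (im.matrix / d)
    idx = np.argmax(scores, axis=2)
    conf = np.take_along_axis(scores, idx[..., None], axis=2)[..., 0]
    return idx, conf


def decode_iterative(
    superpositions: np.ndarray,
    im: ItemMemory,
    perms: PermutationSet,
    truths: Optional[np.ndarray] = None,
    readout: Optional[MMSEReadout] = None,
    feedback: str = "none",
    max_iterations: int = 10,
    chunk: int = 64,
) -> RetrievalResult:
    """Retrieve all positions of a batch of superpositions, with optional feedback.

    ``readout=None`` uses the AM readout; otherwise the trained MMSE
    readout supplies the estimates.  With feedback, estimates are
    re-encoded through the true dictionary and permutations and subtracted
    from the other positions' queries (unit: full scale; soft: scaled by
    the estimate's confidence clipped to [0, 1]); iteration stops when all
    estimated indexes repeat, or at ``max_iterations``.  Batches larger
    than ``chunk`` trials are processed in slices to bound peak memory.
    """
    if feedback not in ("none", "unit", "soft"):
        raise ValueError(f"feedback must be one of none/unit/soft, got {feedback!r}")
    x = np.asarray(superpositions, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    n_trials = x.shape[0]
    if n_trials > chunk:
        parts = []
        for lo in range(0, n_trials, chunk):
            t_part = None if truths is None else np.asarray(truths)[lo : lo + chunk]
            parts.append(
                decode_iterative(
                    x[lo : lo + chunk], im, perms, t_part, readout, feedback, max_iterations, chunk
                )
            )
        est = np.concatenate([p.estimates for p in parts], axis=0)
        weights = np.array([p.estimates.shape[0] for p in parts], dtype=float)
        mean_it = float(np.average([p.mean_iterations for p in parts], weights=weights))
        if truths is not None:
            acc = float(np.mean(est == np.asarray(truths)))
            cap = capacity(acc, est.shape[1], im.dim, im.n_items)
        else:
            acc, cap = float("nan"), float("nan")
        return RetrievalResult(est, acc, cap, mean_it)
    v_count = readout.n_positions if readout is not None else (
        np.asarray(truths).shape[1] if truths is not None else perms.n_perms
    )

    fwd = perms.perms[:v_count]
    est, conf = _estimate_all(x, im, perms, readout, v_count)
    iters = np.ones(n_trials)
    if feedback != "none" and v_count > 1:
        active = np.ones(n_trials, dtype=bool)
        for _ in range(max_iterations - 1):
            if not np.any(active):
                break
            xa = x[active]
            ea = est[active]
            if feedback == "soft":
                scale = np.clip(np.abs(conf[active]), 0.0, 1.0)
            else:
                scale = np.ones_like(conf[active])
            # re-encode Pi_v(e_{q_v}) for all positions of the active trials
            entries = im.vectors[ea]  # (a, V, D)
            reenc = np.take_along_axis(entries, np.broadcast_to(fwd, entries.shape), axis=2)
            reenc = reenc * scale[..., None]
            total = reenc.sum(axis=1)  # (a, D)
            cleaned = xa[:, None, :] - total[:, None, :] + reenc  # (a, V, D)
            if readout is not None:
                scores = np.einsum("avd,vdn->avn", cleaned, readout.matrices[:v_count], optimize=True)
            else:
                inv_idx = perms.inverse_perms[:v_count]
                inv = np.take_along_axis(cleaned, np.broadcast_to(inv_idx, cleaned.shape), axis=2)
                scores = inv @ (im.matrix / im.dim)
            new_est = np.argmax(scores, axis=2)
            new_conf = np.take_along_axis(scores, new_est[..., None], axis=2)[..., 0]
            changed = np.any(new_est != ea, axis=1)
            est[active] = new_est
            conf[active] = new_conf
            iters[active] += 1
            idx_active = np.flatnonzero(active)
            active[idx_active[~changed]] = False

    if truths is not None:
        truths = np.asarray(truths)
        acc = float(np.mean(est == truths))
        cap = capacity(acc, v_count, im.dim, im.n_items)
    else:
        acc = float("nan")
        cap = float("nan")
    return RetrievalResult(
        estimates=est,
        accuracy=acc,
        capacity_bits_per_dim=cap,
        mean_iterations=float(np.mean(iters)),
    )


def capacity(p_c: float, V: int, D: int, N: int) -> float:
    """Operational capacity in bits per dimension at retrieval probability p_c.

    Capacity(p_c) = (V/D) { p_c log2(p_c N)
                            + (1 - p_c) log2( N/(N-1) (1 - p_c) ) },
    with the second term taken as 0 at p_c = 1 (its algebraic limit) and
    the first as 0 at p_c = 0.  At chance level p_c = 1/N both terms cancel
    exactly and the capacity is 0.
    """
    if not 0.0 <= p_c <= 1.0:
        raise ValueError(f"p_c must lie in [0, 1], got {p_c}")
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    first = p_c * np.log2(p_c * N) if p_c > 0.0 else 0.0
    second = (1.0 - p_c) * np.log2(N / (N - 1) * (1.0 - p_c)) if p_c < 1.0 else 0.0
    return float(V / D * (first + second))
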