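"""Foundational multiply-add-permute (MAP) operations on hypervectors.

Hypervectors are plain one-dimensional numpy arrays: *bipolar* vectors hold
values in {-1, +1} (``int8``), *integer* vectors arise from superposing
(element-wise adding) bipolar vectors.  All randomness is driven by
``numpy.random.Generator`` streams derived from integer seeds through
:func:`derived_rng`, so that each component (item memory, permutations,
channel noise, ...) owns an independent, reproducible stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "derived_rng",
    "ItemMemory",
    "ContinuousItemMemory",
    "PermutationSet",
    "make_item_memory",
    "make_cim",
    "cosine",
    "rotate",
    "permute",
    "bundle",
    "bind",
    "bipolarize",
    "random_bipolar",
]

# Fixed sub-stream labels so that e.g. the item memory drawn for seed s is
# independent of the permutation set drawn for the same s.
STREAM_ITEM_MEMORY = 0
STREAM_CIM = 1
STREAM_PERMUTATIONS = 2
STREAM_TIE_BREAKER = 3
STREAM_NOISE = 4
STREAM_DATA = 5
STREAM_INTERFERENCE = 6


def derived_rng(seed: int, *key: int) -> np.random.Generator:
    """Return a generator for the sub-stream ``key`` of master ``seed``.

    Distinct keys yield statistically independent streams for the same
    master seed (via ``SeedSequence`` spawn keys).
    """
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key)))


def random_bipolar(dim: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a Rademacher (i.i.d. fair +/-1) vector of length ``dim``."""
    return (2 * rng.integers(0, 2, size=dim) - 1).astype(np.int8)


def _balanced_bipolar(dim: int, rng: np.random.Generator) -> np.ndarray:
    """Bipolar vector with an exactly equal number of +1 and -1.

    For odd ``dim`` the counts differ by exactly one.
    """
    template = np.ones(dim, dtype=np.int8)
    template[: dim // 2] = -1
    return rng.permutation(template)


@dataclass(frozen=True)
class ItemMemory:
    """Fixed random dictionary of ``n_items`` quasi-orthogonal bipolar vectors.

    ``vectors`` has shape ``(n_items, dim)`` with rows as dictionary entries
    (the matrix E holds them as columns; ``matrix`` exposes that view).
    """

    vectors: np.ndarray
    seed: int
    balanced: bool = True

    @property
    def n_items(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        """The D x N dictionary matrix (entries as columns)."""
        return self.vectors.T

    def __getitem__(self, q: int) -> np.ndarray:
        return self.vectors[q]


@dataclass(frozen=True)
class ContinuousItemMemory:
    """Distance-preserving level dictionary (continuous item memory).

    Level 1 is a random bipolar seed vector; successive levels invert a
    growing, nested set of randomly chosen positions until exactly D/2
    positions are inverted at level L, making the first and last level
    orthogonal.  ``levels[i]`` stores level ``i + 1``.
    """

    levels: np.ndarray
    seed: int

    @property
    def n_levels(self) -> int:
        return self.levels.shape[0]

    @property
    def dim(self) -> int:
        return self.levels.shape[1]

    def __getitem__(self, level_index: int) -> np.ndarray:
        return self.levels[level_index]


@dataclass(frozen=True)
class PermutationSet:
    """V distinct random permutations of D positions, with inverses.

    ``permute(x, v)`` computes ``x[perms[v-1]]`` (1-based block index, as the
    blocks of a code are conventionally numbered).
    """

    perms: np.ndarray  # (V, D) int64, forward index maps
    seed: int
    inverse_perms: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        inv = np.argsort(self.perms, axis=1)
        object.__setattr__(self, "inverse_perms", inv)

    @property
    def n_perms(self) -> int:
        return self.perms.shape[0]

    @property
    def dim(self) -> int:
        return self.perms.shape[1]

    @classmethod
    def random(cls, n_perms: int, dim: int, seed: int) -> "PermutationSet":
        rng = derived_rng(seed, STREAM_PERMUTATIONS)
        perms = np.empty((n_perms, dim), dtype=np.int64)
        seen = set()
        i = 0
        while i < n_perms:
            p = rng.permutation(dim)
            key = p.tobytes()
            if key in seen:  # pragma: no cover - collisions essentially never occur
                continue
            seen.add(key)
            perms[i] = p
            i += 1
        return cls(perms=perms, seed=seed)

    @classmethod
    def identity(cls, n_perms: int, dim: int) -> "PermutationSet":
        """All-identity set (useful for single-block codes and worked examples)."""
        perms = np.tile(np.arange(dim, dtype=np.int64), (n_perms, 1))
        return cls(perms=perms, seed=-1)

    def apply(self, x: np.ndarray, v: int, inverse: bool = False) -> np.ndarray:
        if not 1 <= v <= self.n_perms:
            raise ValueError(f"block index v={v} out of range 1..{self.n_perms}")
        idx = self.inverse_perms[v - 1] if inverse else self.perms[v - 1]
        return np.asarray(x)[..., idx]


def make_item_memory(n_items: int, dim: int, seed: int, balanced: bool = True) -> ItemMemory:
    """Build a random dictionary of ``n_items`` bipolar vectors of length ``dim``.

    With ``balanced=True`` (default) every entry has an exactly equal number
    of +1 and -1 (off by one for odd ``dim``); with ``balanced=False``
    entries are i.i.d. Rademacher.
    """
    if n_items < 1:
        raise ValueError(f"n_items must be >= 1, got {n_items}")
    if dim < 2:
        raise ValueError(f"dim must be >= 2, got {dim}")
    rng = derived_rng(seed, STREAM_ITEM_MEMORY)
    if balanced:
        vectors = np.stack([_balanced_bipolar(dim, rng) for _ in range(n_items)])
    else:
        vectors = random_bipolar(n_items * dim, rng).reshape(n_items, dim)
    return ItemMemory(vectors=vectors, seed=seed, balanced=balanced)


def make_cim(n_levels: int, dim: int, seed: int) -> ContinuousItemMemory:
    """Build a continuous item memory with ``n_levels`` levels of length ``dim``.

    Cumulative flips at level ``l`` (1-based) are
    ``round((l - 1) / (L - 1) * dim / 2)`` positions of a single seeded
    random ordering, so flipped sets are nested, the similarity profile
    decays linearly, and level L is orthogonal to level 1.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    if dim % 2 != 0:
        raise ValueError(f"dim must be even for an orthogonal extreme level, got {dim}")
    rng = derived_rng(seed, STREAM_CIM)
    base = random_bipolar(dim, rng)
    order = rng.permutation(dim)
    levels = np.empty((n_levels, dim), dtype=np.int8)
    for l in range(1, n_levels + 1):
        flips = round((l - 1) / (n_levels - 1) * dim / 2)
        vec = base.copy()
        vec[order[:flips]] *= -1
        levels[l - 1] = vec
    return ContinuousItemMemory(levels=levels, seed=seed)


def cosine(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine similarity <x, y> / (||x|| ||y||)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(x, y) / (nx * ny))


def rotate(x: np.ndarray, r: int) -> np.ndarray:
    """Cyclic right shift by ``r`` positions: ``rotate(x, r)[i] = x[(i - r) mod D]``.

    ``rotate(x, -r)`` is the exact inverse.
    """
    return np.roll(np.asarray(x), int(r), axis=-1)


def permute(x: np.ndarray, pset: PermutationSet, v: int, inverse: bool = False) -> np.ndarray:
    """Apply the ``v``-th permutation (1-based) of ``pset`` to ``x``."""
    return pset.apply(x, v, inverse=inverse)


def bundle(xs: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise sum (superposition) of equally sized vectors."""
    if len(xs) == 0:
        raise ValueError("cannot bundle an empty list of vectors")
    arrs = [np.asarray(x) for x in xs]
    dims = {a.shape for a in arrs}
    if len(dims) != 1:
        raise ValueError(f"all vectors must share one shape, got {sorted(dims)}")
    out = np.zeros(arrs[0].shape, dtype=np.int64)
    for a in arrs:
        out += a
    return out


def bind(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Element-wise product; for bipolar inputs the result is bipolar and
    quasi-orthogonal to both operands.  Self-inverse: bind(bind(x, y), y) = x."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return (x * y).astype(np.int8) if x.dtype == np.int8 and y.dtype == np.int8 else x * y


def bipolarize(x: np.ndarray, tie_breaker: np.ndarray) -> np.ndarray:
    """Element-wise sign with deterministic tie-breaking.

    Zero entries take the sign of ``tie_breaker`` at that position (the
    conventional fix for superpositions of an even number of vectors).
    """
    x = np.asarray(x)
    t = np.asarray(tie_breaker)
    if x.shape[-1] != t.shape[-1]:
        raise ValueError(f"tie_breaker dim {t.shape[-1]} does not match input dim {x.shape[-1]}")
    out = np.sign(x).astype(np.int8)
    zero = out == 0
    if np.any(zero):
        out = np.where(zero, np.broadcast_to(t, x.shape), out).astype(np.int8)
    return out
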