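"""Simulation harnesses: BER sweeps, retrieval/capacity sweeps, NCC grids.

Every function returns a tidy :class:`pandas.DataFrame` with one row per
experimental cell, carrying the full parameter set alongside the metrics so
any row can be re-run from its own fields.  Proportions come with Wilson
confidence half-widths (the paper-style plots report none, but the harness
should know its own Monte-Carlo error).
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from hdmod import channel
from hdmod.codec import CodeConfig, Decoder, DecoderConfig, encode, make_codebooks, throughput
from hdmod.core import (
    STREAM_DATA,
    STREAM_INTERFERENCE,
    STREAM_NOISE,
    PermutationSet,
    derived_rng,
    make_cim,
    make_item_memory,
)
from hdmod.ncc import (
    ClassPrototypes,
    NccConfig,
    NccEncoder,
    classify,
    mse_db,
    reconstruct_stream,
)
from hdmod.readout import (
    MMSEReadout,
    decode_iterative,
    encode_superpositions,
    random_index_batch,
    train_mmse,
)

__all__ = [
    "wilson_halfwidth",
    "run_ber_sweep",
    "run_retrieval_sweep",
    "perfect_retrieval_corner",
    "run_ncc_grid",
    "run_reconstruction_grid",
    "environment_record",
]


def wilson_halfwidth(successes: int, n: int, z: float = 1.96) -> float:
    """Half-width of the Wilson score interval for a binomial proportion."""
    if n <= 0:
        return float("nan")
    p = successes / n
    denom = 1.0 + z**2 / n
    half = (z / denom) * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
    return float(half)


def environment_record() -> Dict[str, str]:
    """Library versions for result provenance."""
    import scipy

    import hdmod

    return {
        "hdmod": hdmod.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }


# ---------------------------------------------------------------------------
# channel-code sweeps
# ---------------------------------------------------------------------------


def run_ber_sweep(
    config: CodeConfig,
    decoders: Dict[str, DecoderConfig],
    snr_db_grid: Sequence[float],
    n_blocks: int,
    seed: int = 0,
    dtype=np.float32,
) -> pd.DataFrame:
    """Monte-Carlo BER/iteration sweep of the integer HDM code over AWGN.

    All decoders in ``decoders`` (name -> config) see the *same* received
    vectors at each SNR point, so decoder comparisons are paired.  Returns
    one row per (snr, decoder) with bit/block error rates, mean iteration
    counts and Wilson half-widths.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    im, perms, _ = make_codebooks(config)
    engines = {name: Decoder(im, perms, config, dcfg, dtype=dtype) for name, dcfg in decoders.items()}
    k = config.n_bits
    r = throughput(config)
    data_rng = derived_rng(seed, STREAM_DATA)
    rows = []
    for snr_i, snr_db in enumerate(snr_db_grid):
        noise_rng = derived_rng(seed, STREAM_NOISE, snr_i)
        stats = {name: {"bit_errors": 0, "block_errors": 0, "iterations": 0.0} for name in engines}
        for _ in range(n_blocks):
            bits = data_rng.integers(0, 2, size=k)
            x = encode(bits, im, perms, config)
            y = channel.awgn(x, snr_db, signal_power=config.n_superposed, rng=noise_rng)
            u = "".join("01"[b] for b in bits)
            for name, dec in engines.items():
                res = dec.decode(y)
                nerr = sum(a != b for a, b in zip(res.bits, u))
                stats[name]["bit_errors"] += nerr
                stats[name]["block_errors"] += int(nerr > 0)
                stats[name]["iterations"] += res.iterations
        for name, s in stats.items():
            total_bits = n_blocks * k
            rows.append(
                {
                    "snr_db": snr_db,
                    "ebn0_db": channel.ebn0_from_snr(snr_db, r),
                    "decoder": name,
                    "dim": config.dim,
                    "im_size": config.im_size,
                    "n_superposed": config.n_superposed,
                    "throughput": r,
                    "n_blocks": n_blocks,
                    "n_bits": total_bits,
                    "bit_errors": s["bit_errors"],
                    "ber": s["bit_errors"] / total_bits,
                    "ber_halfwidth": wilson_halfwidth(s["bit_errors"], total_bits),
                    "block_errors": s["block_errors"],
                    "bler": s["block_errors"] / n_blocks,
                    "mean_iterations": s["iterations"] / n_blocks,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# noise-free retrieval / capacity sweeps
# ---------------------------------------------------------------------------


def _mmse_readout_for(
    im, perms, v_count: int, n_train: int, seed: int
) -> MMSEReadout:
    rng = derived_rng(seed, STREAM_DATA, v_count)
    train_idx = random_index_batch(n_train, v_count, im.n_items, rng)
    train_x = encode_superpositions(train_idx, im, perms)
    return train_mmse(train_x, train_idx, seed=seed)


def _retrieval_point(
    im,
    perms,
    v_count: int,
    readout: str,
    feedback: str,
    trials: int,
    seed: int,
    n_train: Optional[int],
):
    rng = derived_rng(seed, STREAM_DATA, v_count, 1)
    truths = random_index_batch(trials, v_count, im.n_items, rng)
    x = encode_superpositions(truths, im, perms)
    ro = None
    if readout == "mmse":
        n_train = n_train or 20 * im.dim
        ro = _mmse_readout_for(im, perms, v_count, n_train, seed)
    return decode_iterative(x, im, perms, truths=truths, readout=ro, feedback=feedback)


def run_retrieval_sweep(
    dim: int,
    im_sizes: Sequence[int],
    v_grid: Sequence[int],
    readout: str = "am",
    feedback: str = "none",
    trials: int = 200,
    seed: int = 0,
    n_train: Optional[int] = None,
) -> pd.DataFrame:
    """Accuracy and operational capacity over (N, V) grids, noise-free.

    Plain superpositions (no sign or rotation encoding); ``readout`` is
    'am' or 'mmse', ``feedback`` one of none/unit/soft.
    """
    if readout not in ("am", "mmse"):
        raise ValueError(f"readout must be 'am' or 'mmse', got {readout!r}")
    v_max = int(max(v_grid))
    rows = []
    for n_items in im_sizes:
        im = make_item_memory(n_items, dim, seed)
        perms = PermutationSet.random(v_max, dim, seed)
        for v_count in v_grid:
            res = _retrieval_point(im, perms, int(v_count), readout, feedback, trials, seed, n_train)
            rows.append(
                {
                    "readout": readout,
                    "feedback": feedback,
                    "dim": dim,
                    "im_size": n_items,
                    "n_superposed": int(v_count),
                    "trials": trials,
                    "accuracy": res.accuracy,
                    "accuracy_halfwidth": wilson_halfwidth(
                        int(round(res.accuracy * trials * v_count)), trials * int(v_count)
                    ),
                    "capacity_bits_per_dim": res.capacity_bits_per_dim,
                    "mean_iterations": res.mean_iterations,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


def perfect_retrieval_corner(
    dim: int,
    im_size: int,
    readout: str = "am",
    feedback: str = "none",
    trials: int = 200,
    seed: int = 0,
    coarse_step: int = 16,
    v_max: int = 300,
    n_train: Optional[int] = None,
) -> int:
    """Largest V at which every position of every trial is retrieved correctly.

    Coarse upward scan (step ``coarse_step``) brackets the first imperfect
    V, then a unit-step scan inside the bracket locates the corner.
    """
    im = make_item_memory(im_size, dim, seed)
    perms = PermutationSet.random(v_max, dim, seed)

    def perfect(v_count: int) -> bool:
        res = _retrieval_point(im, perms, v_count, readout, feedback, trials, seed, n_train)
        return res.accuracy == 1.0

    last_good = 0
    first_bad = None
    for v_count in range(1, v_max + 1, coarse_step):
        if perfect(v_count):
            last_good = v_count
        else:
            first_bad = v_count
            break
    if first_bad is None:
        return last_good
    for v_count in range(last_good + 1, first_bad):
        if perfect(v_count):
            last_good = v_count
        else:
            break
    return last_good


# ---------------------------------------------------------------------------
# NCC robustness and reconstruction grids
# ---------------------------------------------------------------------------


def run_ncc_grid(
    encoder: NccEncoder,
    prototypes: ClassPrototypes,
    queries: np.ndarray,
    labels: np.ndarray,
    snr_db_grid: Sequence[float],
    interferer_grid: Sequence[int] = (0,),
    bipolarize_query: bool = False,
    seed: int = 0,
    interferer_pool_size: int = 64,
) -> pd.DataFrame:
    """Classification accuracy over an (SNR, interferer-count) grid.

    ``queries`` are encoded bipolar n-grams (one per decision).  Interferers
    are modelled as unrelated nodes with their *own* encoder dictionaries,
    each contributing an equal-power, symbol-synchronous bipolar n-gram
    drawn from a per-node pool of random transmissions.
    """
    queries = np.asarray(queries)
    labels = np.asarray(labels)
    n_queries = queries.shape[0]
    max_j = int(max(interferer_grid))
    pools = []
    for j in range(max_j):
        node = NccEncoder(
            NccConfig(
                dim=encoder.config.dim,
                n_levels=encoder.config.n_levels,
                n_channels=encoder.config.n_channels,
                ngram_size=encoder.config.ngram_size,
                seed=int(derived_rng(seed, STREAM_INTERFERENCE, j).integers(0, 2**31)),
            )
        )
        pool_rng = derived_rng(seed, STREAM_INTERFERENCE, j, 1)
        pool = np.stack(
            [node.random_transmission(pool_rng) for _ in range(interferer_pool_size)]
        )
        pools.append(pool)
    rows = []
    for snr_i, snr_db in enumerate(snr_db_grid):
        for n_interf in interferer_grid:
            rng = derived_rng(seed, STREAM_NOISE, snr_i, int(n_interf))
            y = queries.astype(np.float64)
            for j in range(int(n_interf)):
                pick = rng.integers(0, interferer_pool_size, size=n_queries)
                y = y + pools[j][pick]
            if np.isfinite(snr_db):
                y = y + rng.normal(0.0, np.sqrt(1.0 / channel.snr_linear(snr_db)), size=y.shape)
            pred = np.atleast_1d(classify(y, prototypes, bipolarize_query=bipolarize_query))
            correct = int(np.sum(pred == labels))
            rows.append(
                {
                    "snr_db": snr_db,
                    "n_interferers": int(n_interf),
                    "bipolar_query": bipolarize_query,
                    "dim": encoder.config.dim,
                    "n_queries": n_queries,
                    "correct": correct,
                    "accuracy": correct / n_queries,
                    "accuracy_halfwidth": wilson_halfwidth(correct, n_queries),
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


def run_reconstruction_grid(
    features: np.ndarray,
    dims: Sequence[int],
    snr_db_grid: Sequence[float],
    feedbacks: Sequence[str] = ("none", "soft"),
    n_levels: int = 128,
    seed: int = 0,
    max_iterations: int = 10,
) -> pd.DataFrame:
    """Feature-reconstruction MSE (dB) over a (dimension, SNR, feedback) grid.

    Each frame's 64 features are spatially encoded at dimension D,
    transmitted through AWGN with per-dimension signal power 64 (the
    superposition of 64 bipolar level vectors), and reconstructed with the
    requested feedback mode; the MSE is measured against the original
    (pre-quantization) features.
    """
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    n_channels = features.shape[1]
    rows = []
    for d in dims:
        cfg = NccConfig(dim=int(d), n_levels=n_levels, n_channels=n_channels, seed=seed)
        enc = NccEncoder(cfg)
        x = enc.spatial(features)
        for snr_i, snr_db in enumerate(snr_db_grid):
            noise_rng = derived_rng(seed, STREAM_NOISE, int(d), snr_i)
            y = channel.awgn(x, snr_db, signal_power=n_channels, rng=noise_rng)
            for fb in feedbacks:
                rec = reconstruct_stream(
                    y, enc.cim, feedback=fb, max_iterations=max_iterations, n_channels=n_channels
                )
                rows.append(
                    {
                        "dim": int(d),
                        "snr_db": snr_db,
                        "feedback": fb,
                        "n_frames": features.shape[0],
                        "mse_db": mse_db(rec, features),
                        "seed": seed,
                    }
                )
    return pd.DataFrame(rows)
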