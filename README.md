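# hdmod

Integer hyperdimensional modulation, learned MMSE superposition readout, and
near-channel classification of multichannel EMG — a single representational
stack in which the same long random vectors carry both a channel code and a
classifier.

## The problem

Wireless sensor nodes conventionally stack source coding, channel coding and
machine-learning inference as separate layers, each with its own
representation. Hyperdimensional (HD) computing offers an alternative:
information is spread holographically over very long (10³–10⁴ dimensional)
random vectors manipulated with three operations — element-wise
multiplication (binding), element-wise addition (bundling/superposition) and
permutation. Such vectors tolerate heavy noise, so one encoding can serve as
a modulation scheme *and* feed a classifier directly at the receiver, with
no decoding stage in between ("near-channel classification", NCC).

This package implements that stack for:

- **channel coding** — an integer HD modulation: a k-bit string is split
  into V blocks, each selecting a dictionary entry e_q ∈ {−1,+1}^D, a cyclic
  rotation ρ^r and a sign s; the transmitted vector is
  x = Σ_v Π_v(s_v · ρ^{r_v}(e_{q_v})) with block-unique random permutations
  Π_v. Throughput: r = V(log₂N + log₂D + 1)/D bits per channel use.
  Decoding alternates associative-memory (AM) searches over all (q, r)
  pairs with iterative interference cancellation, subtracting the other
  blocks' re-encoded estimates either at full scale (*unit feedback*) or
  scaled by the previous estimate's confidence ĉ clipped to one
  (*soft feedback*). Fixed-point (m.q) and readout (V′-level) quantization
  model low-precision hardware decoders.
- **superposition retrieval** — recovery of the symbols of plain permuted
  superpositions with either the AM readout ĉ_v = (1/D)Eᵀ Π_v^{-1}(x) or
  per-position MMSE readout matrices F_v trained by least squares from
  (x, one-hot) pairs alone, plus the operational-capacity statistic
  Capacity(p_c) = (V/D){p_c log₂(p_c N) + (1−p_c) log₂(N/(N−1)(1−p_c))}.
- **EMG gesture pipeline** — 64-channel features (10 frames/s) quantized to
  128 levels, embedded with a distance-preserving continuous item memory,
  rotated by channel index and superposed; classification binds five
  consecutive bipolarized frames into a 5-gram and matches class
  prototypes; transmission mode sends the integer spatial vector and
  reconstructs all 64 features with the same iterative feedback decoder.
- **synthetic data** — a seeded generator of 5-class, 64-channel gesture
  feature streams (and raw 1 kS/s signals) with controllable separability
  and noise, so every stage is testable without downloading recordings.

## Worked example

```python
import numpy as np
from hdmod import CodeConfig, DecoderConfig, encode, decode, awgn, throughput
from hdmod.codec import make_codebooks

config = CodeConfig(dim=512, im_size=512, n_superposed=7, seed=1)
print(f"k = {config.n_bits} bits, r = {throughput(config):.4f}")
# k = 133 bits, r = 0.2598

im, perms, _ = make_codebooks(config)
rng = np.random.default_rng(0)
u = "".join("01"[b] for b in rng.integers(0, 2, size=config.n_bits))
x = encode(u, im, perms, config)            # integer vector, entries odd, |x| <= 7
y = awgn(x, snr_db=0.0, signal_power=7, rng=1)
res = decode(y, im, perms, config, DecoderConfig(feedback="soft"))
print(res.bits == u, res.iterations)
# True 3
```

At 0 dB SNR the 1/4-rate configuration decodes essentially error-free
(BER ≈ 10⁻⁴) in about 2.4 passes on average.

The EMG pipeline end to end, on synthetic data:

```python
from hdmod.ncc import NccConfig, NccEncoder, train_prototypes, classify
from hdmod.synth import SyntheticConfig, generate_features

scfg = SyntheticConfig(seed=11)
train_f, train_l = generate_features(scfg, noise_seed=111)
test_f,  test_l  = generate_features(scfg, noise_seed=211)
enc = NccEncoder(NccConfig(dim=10000, seed=11))
g_tr, l_tr = enc.encode_trials(train_f, train_l, scfg.frames_per_trial)
g_te, l_te = enc.encode_trials(test_f,  test_l,  scfg.frames_per_trial)
protos = train_prototypes(g_tr, l_tr, enc.tie_breaker)
print(round(float(np.mean(classify(g_te.astype(float), protos) == l_te)), 4))
# 0.9508
```

Adding channel noise at 0 dB SNR leaves that accuracy essentially unchanged
(0.95 on the same stream); the transmission mode reconstructs the features
to the quantizer floor (≈ −52 dB MSE) in the noise-free channel.

Command-line equivalents: `hdm encode|decode|ber|capacity` and
`ncc synth|train|classify|grid|reconstruct|reconstruct-grid`.

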