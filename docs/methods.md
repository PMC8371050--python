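# Methods

This note documents the models implemented in `hdmod`, the parameter and
design choices that were genuinely open, the numerical conventions, and what
the synthetic-data experiments do and do not establish.

## Hypervector primitives (`hdmod.core`)

All information is carried by D-dimensional vectors. Bipolar vectors have
entries in {−1, +1}; superposing (element-wise adding) V of them yields an
integer vector whose entries share V's parity and lie in [−V, V]. The three
MAP operations are binding (element-wise product; self-inverse on bipolar
inputs and quasi-orthogonal to both operands), bundling (element-wise sum;
similar to each addend), and permutation (random reordering, or the
hardware-friendly special case of a cyclic rotation). Similarity is cosine.

Conventions fixed for reproducibility:

- **Rotation direction.** `rotate(x, r)[i] = x[(i − r) mod D]` (a right
  shift, `numpy.roll`); `rotate(·, −r)` is the exact inverse. Any
  consistent convention is equivalent.
- **Item memory balance.** Dictionary entries are drawn by shuffling a
  half-and-half template, so every entry has an exactly equal number of +1
  and −1 (difference 1 for odd D). I.i.d. Rademacher entries are available
  as an option (`balanced=False`); exact balance is the default because it
  realizes the "equal number" construction literally and removes a small
  DC term from all inner products.
- **Continuous item memory (CiM).** Level 1 is a random bipolar vector;
  level l inverts the first `round((l−1)/(L−1) · D/2)` positions of one
  seeded random ordering. The flipped sets are therefore nested, the
  similarity profile is exactly linear, cosine(level 1, level l) =
  1 − 2·flips(l)/D, and level L is exactly orthogonal to level 1 (even D is
  required). A per-level increment of D/(2L) would end short of D/2 flips;
  the endpoint (orthogonal extremes) is the defining property and is what
  the implementation guarantees.
- **Tie-breaking in bipolarization.** Zero entries of a superposition take
  the sign of one fixed random tie-breaker vector drawn per configuration
  seed — deterministic across runs, unlike per-call random tie-breaking.
- **Randomness.** One master seed per configuration; every component (item
  memory, CiM, permutations, tie-breaker, channel noise, payload data)
  draws from an independently derived `SeedSequence` sub-stream, so any
  single component can be regenerated without replaying the others.

## Integer HDM codec (`hdmod.codec`)

A k-bit payload is split into V blocks of log₂N + log₂D + 1 bits
(throughput r = V(log₂N + log₂D + 1)/D). Each block is sliced (q | r | s),
each slice read MSB-first, the sign bit mapped as s = 2b − 1, and the block
vector s · ρ^r(e_q) permuted with a block-unique random permutation before
superposition. D and N are powers of two so both index ranges are filled
exactly.

Decoding repeats two stages until the index estimates of all V blocks are
unchanged between consecutive passes (or a cap of 10 passes is reached;
means are ≈ 2–3):

1. **Estimation.** For block v the query is the received vector minus the
   re-encoded estimates of all *other* blocks from the previous pass
   (all-zero on the first pass). After inverse permutation, the AM search
   computes ĉ[q, r] = (1/D)⟨ρ^{−r}(y_v), e_q⟩ for all N·D pairs and takes
   the (q, r) maximizing |ĉ|, with the sign of the winning entry as ŝ and
   |ĉ| as the confidence.
2. **Feedback.** Unit feedback subtracts estimates at full scale; soft
   feedback scales each subtracted estimate by min(|ĉ|, 1). Clipping at
   one matters: confidences above one would otherwise amplify the
   subtraction, and attenuating low-confidence estimates is precisely what
   damps the oscillations unit feedback can exhibit.

Estimation uses the previous pass's feedback for *all* blocks (Jacobi-style
update, matching the cancellation equations). The iteration count reported
includes the final, confirming pass; a single-block code (V = 1) terminates
after one pass since there is no interference to cancel. With this
convention the unit-feedback decoder of the 1/4-rate configuration
(V=7, N=512, D=512) averages ≈ 2.44–2.46 passes at 0 dB SNR.

**AM search implementation.** The (q, r) scan is a set of circular
cross-correlations and is evaluated with real FFTs (dictionary spectra
precomputed). The transform is an implementation detail: ties of the
metric — exact multiples of 1/D for integer queries — are resolved to the
lexicographically smallest (q, r) using a tolerance of 10⁻⁹ on the
floating-point correlation values, which makes the FFT path index-identical
to the direct scan (tested on adversarial integer queries). Monte-Carlo
harnesses may run the FFTs in float32; with continuous channel noise exact
ties occur with probability zero, so this changes nothing statistically.

**Quantized decoders.** Readout quantization maps each query element to
the nearest value in {−V′, −V′+2, …, V′} (the support of a noise-free
V′-superposition), halfway ties toward the smaller magnitude. Fixed-point
m.q quantization rounds to step 2^{−q} with ties away from zero and clips
symmetrically at ±(2^m − 2^{−q}); it is applied to the received vector and
to the soft-feedback scale, where q = 1 collapses the scale to {0, 0.5, 1}.
At 2 dB SNR the 4.1 fixed-point soft decoder's BER is statistically
indistinguishable from the floating-point decoder's.

## Channel models (`hdmod.channel`)

AWGN adds i.i.d. Gaussian noise of per-dimension variance P/SNR, with P the
per-dimension signal power: V for an integer superposition of V bipolar
vectors, 1 for a bipolar transmission. E_b/N_0 := SNR/(2r). Interference
from J unrelated nodes adds J independently encoded, equal-power,
symbol-synchronous bipolar vectors; interferers use their own dictionaries
(worst-case alignment, no fading, no power imbalance — none of which the
model attempts to capture).

## MMSE readout and operational capacity (`hdmod.readout`)

For plain permuted superpositions (no sign/rotation encoding), a learned
readout replaces the dictionary: per position v, F_v minimizes the mean
squared error between F_vᵀx and the one-hot symbol vector over R training
pairs. The objective is convex, so the closed-form normal-equations
solution (with ridge 10⁻⁶ for conditioning) equals converged (stochastic)
gradient descent; a full-batch gradient-descent oracle confirms this in the
tests. Default R = 20·D samples. Training touches only (x, c_v) pairs —
neither the dictionary nor the permutations — but *feedback* decoding with
the MMSE readout re-encodes estimates through the true dictionary for
subtraction, a documented departure from the dictionary-free inference
mode (the cancellation equations require reconstructed vectors).

Retrieval probability p_c is the fraction of correctly retrieved positions
pooled over trials. Operational capacity,
Capacity(p_c) = (V/D){p_c log₂(p_c N) + (1−p_c) log₂(N/(N−1)(1−p_c))},
is 0 at chance (p_c = 1/N, both terms cancel algebraically) and the second
term is taken as its limit 0 at p_c = 1.

**Corner measurement.** "The largest V decodable with 100 % accuracy" is an
experiment-size-dependent statistic: with only a few hundred trials,
per-retrieval error rates of ~10⁻⁴ are invisible and the zero-error corner
overshoots. Corners are therefore measured with 5000 superpositions per V
(≈ 10⁵–10⁶ retrievals near the corners of interest), the budget at which a
retrieval curve visibly leaves 100 %; the same budget is applied to both
readouts. At D=500, N=5 this yields V ≈ 12 for the plain AM readout and
V ≈ 132–134 for the MMSE readout. With unit feedback the MMSE readout
holds perfect retrieval to V ≈ 260 and its capacity peaks at ≈ 1.20
bits/dimension (measured on a coarse V grid with 100 trials per point).

## EMG pipeline (`hdmod.ncc`)

Preprocessing (causal, per channel, at 1 kS/s): 60 Hz notch (Q = 50),
8th-order Butterworth band-pass 1–200 Hz, rectification, 100-tap moving
average, decimation by 100 → 10 frames/s, then division by the channel's
95 % training quantile. Features land in [0, 1] with ~5 % overshoot,
clamped at quantization.

Encoding: features are quantized uniformly on [0, 1] to L = 128 levels
(level = clamp(⌊f·L⌋ + 1, 1, L)), embedded with the CiM, cyclically rotated
by the channel index (0–63; the minimal channel-dependent permutation, and
rotations are explicitly the hardware-friendly choice), and superposed.
Classification bipolarizes five consecutive spatial vectors and binds them
into a 5-gram — the newest frame unpermuted, the frame i steps back under a
fixed random permutation Π_i — and emits one decision per frame (every
100 ms); n-grams never span trial boundaries. Class prototypes accumulate
all training n-grams per class and bipolarize the sum. Queries are matched
by cosine; optionally the query is bipolarized first (Hamming-equivalent
search), which costs accuracy below 0 dB SNR. Transmission mode sends the
integer spatial vector (signal power 64) and reconstructs each channel by
de-rotating the received vector and searching the L CiM levels, with the
same iterative feedback machinery as the codec (no rotation or sign
search); estimated levels map to bin centers (l − 0.5)/L, so a noise-free
reconstruction errs by at most 1/L per channel and the MSE floor is the
uniform-quantizer value ≈ −52 dB. Both modes share one spatial encoder
object — byte-identical CiM and rotations — by construction and by test.

EMG-side throughput is r = (64 channels · 7 bits · 5 gram)/D = 2240/D:
compression for D < 2240 (4.375 at D = 512), 1.094 at D = 2048.

## Synthetic gesture streams (`hdmod.synth`)

The generator emulates 5-class (rest + 4 gestures), 64-channel recordings
from a 16×4 electrode grid: 3 s trials at 10 frames/s, 10 trials per class,
classes cycling across runs. Each active class's spatial template mixes a
Gaussian random field *common* to all gestures (shared forearm musculature)
with a class-unique field, weighted by `separability`, smoothed over the
grid so neighbouring electrodes co-activate, and rescaled to [0.15, 0.9].
Trials modulate the template with an onset–hold–offset envelope (0.5 s
linear ramps) plus additive amplitude noise, clipped to [0, 1]. The raw
generator drives a 20–150 Hz band-limited Gaussian carrier with the same
envelope and adds 60 Hz mains pickup.

Defaults were calibrated once and frozen: separability 0.3 and noise 0.05
put the noise-free pipeline accuracy at D = 10000 in the mid-90 % range
with errors concentrated on the rest-like ramp frames near trial
boundaries — the transition-dominated error mode of real gesture streams —
which is what gives the pipeline its characteristic robustness (accuracy at
0 dB within 1 % of noise-free; < 10 % drop with 6 equal-power interferers
at D = 2048). Amplitude noise alone cannot produce that regime: it creates
marginal samples everywhere and makes accuracy degrade smoothly with
channel noise instead.

What passing these tests shows: the encoder/decoder/classifier chain is
correct and its robustness *trends* (dimension, SNR, interferer orderings)
behave as on real data. What it does not show: absolute accuracies on real
recordings, subject/session variability, electrode shift, or motor-unit
physiology — none of which the generator models.

## Monte-Carlo sizes and numerical notes

- BER points: harness default 10³ blocks (CLI), comparisons in the test
  suite use 10⁴ blocks (fixed-point vs float, paired noise) and 500 blocks
  (soft vs unit ordering, paired); iteration counts use 2000 codewords.
- Retrieval corners: 5000 trials per V (see above); capacity peak: 100
  trials per point on the grid {150, 200, 240, 250, 260, 270, 280, 300}.
- Wilson 95 % half-widths accompany all proportions.
- Degenerate inputs: cosine of a zero vector, empty bundles, out-of-range
  indexes and mismatched shapes raise `ValueError`; identical
  reconstructions report −∞ dB MSE explicitly.
- The feedback decoders are not monotone improvements at very low SNR/SIR:
  when most estimates are wrong, subtraction adds interference (visible as
  the steep post-corner collapse in retrieval and as unit feedback
  occasionally under-performing no feedback near 0 dB in reconstruction;
  soft feedback is the safe default).

## Known limitations

- No CRC/list decoding, no rate matching, no fading or asynchronous
  interference models.
- The MMSE readout stores V matrices of D×N floats; memory grows linearly
  in V (this is inherent to per-position readouts).
- Decoding complexity is dominated by the N·D correlation per block; the
  FFT path is O(N·D log D) per block per pass on a single core.
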