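"""EMG pipeline: preprocessing, encoding, classification, reconstruction."""

import numpy as np
import pytest

from hdmod import channel
from hdmod.core import PermutationSet, cosine, make_cim, random_bipolar
from hdmod.ncc import (
    ClassPrototypes,
    NccConfig,
    NccEncoder,
    classify,
    emg_envelope,
    emg_throughput,
    fit_quantiles,
    mse_db,
    preprocess_emg,
    quantize_features,
    reconstruct_stream,
    spatial_encode,
    temporal_encode,
    train_prototypes,
)


class TestPreprocessing:
    def test_notch_suppresses_mains(self):
        t = np.arange(5000) / 1000.0
        out = emg_envelope(np.sin(2 * np.pi * 60.0 * t)[:, None])
        assert np.all(np.abs(out[5:]) < 0.1)  # >= 20 dB below unit amplitude

    def test_zero_input_zero_features(self):
        out = emg_envelope(np.zeros((3000, 4)))
        assert np.allclose(out, 0.0)

    def test_frame_rate_is_input_rate_over_100(self):
        out = emg_envelope(np.random.default_rng(0).normal(size=(5000, 2)))
        assert out.shape == (50, 2)

    def test_normalization_requires_quantiles(self):
        raw = np.random.default_rng(1).normal(size=(2000, 2))
        with pytest.raises(ValueError):
            preprocess_emg(raw, None)
        q = fit_quantiles(raw)
        feats = preprocess_emg(raw, q)
        assert np.mean(feats <= 1.0) >= 0.9  # ~95% of frames inside [0, 1]


class TestQuantizer:
    @pytest.mark.parametrize("f,expected", [(0.0, 1), (1.0, 128), (0.5 - 1e-9, 64), (-0.3, 1), (1.7, 128)])
    def test_level_boundaries(self, f, expected):
        assert quantize_features(np.array([f]))[0] == expected

    def test_bin_width(self):
        f = np.arange(128) / 128.0 + 1e-9
        assert np.array_equal(quantize_features(f), np.arange(1, 129))


class TestSpatialTemporalEncoding:
    def test_spatial_parity_and_range(self):
        cim = make_cim(128, 256, seed=0)
        levels = np.random.default_rng(2).integers(1, 129, size=64)
        x = spatial_encode(levels, cim)
        assert np.all(np.abs(x) <= 64)
        assert np.all(x % 2 == 0)

    def test_spatial_distance_preservation(self):
        """A one-level change in one channel perturbs the superposition far
        less than an extreme-level change."""
        cim = make_cim(128, 8192, seed=1)
        levels = np.full(64, 64)
        near, far = levels.copy(), levels.copy()
        near[10] += 1
        far[10] = 127
        x = spatial_encode(levels, cim)
        assert cosine(x, spatial_encode(near, cim)) > cosine(x, spatial_encode(far, cim))

    def test_ngram_bipolar_and_order_sensitive(self):
        cim = make_cim(128, 10000, seed=2)
        perms = PermutationSet.random(4, 10000, seed=2)
        tie = random_bipolar(10000, np.random.default_rng(3))
        rng = np.random.default_rng(4)
        frames = [spatial_encode(rng.integers(1, 129, size=64), cim) for _ in range(5)]
        g = temporal_encode(frames, tie, perms)
        assert set(np.unique(g)) <= {-1, 1}
        g_rev = temporal_encode(frames[::-1], tie, perms)
        assert abs(cosine(g, g_rev)) < 0.05
        assert np.array_equal(g, temporal_encode(frames, tie, perms))  # deterministic

    def test_ngram_frame_count_checked(self):
        cim = make_cim(8, 64, seed=3)
        perms = PermutationSet.random(1, 64, seed=3)
        tie = random_bipolar(64, np.random.default_rng(5))
        with pytest.raises(ValueError):
            temporal_encode([cim.levels[0]] * 3, tie, perms)


class TestPrototypesAndClassification:
    def test_single_sample_prototype_is_the_sample(self):
        rng = np.random.default_rng(6)
        samples = np.stack([random_bipolar(512, rng) for _ in range(3)])
        tie = random_bipolar(512, rng)
        protos = train_prototypes(samples, np.arange(3), tie)
        assert np.array_equal(protos.vectors, samples)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(7)
        samples = np.stack([random_bipolar(256, rng) for _ in range(6)])
        labels = np.array([0, 0, 1, 1, 2, 2])
        tie = random_bipolar(256, rng)
        a = train_prototypes(samples, labels, tie)
        b = train_prototypes(np.tile(samples, (3, 1)), np.tile(labels, 3), tie)
        assert np.array_equal(a.vectors, b.vectors)

    def test_prototype_classifies_itself(self):
        rng = np.random.default_rng(8)
        protos = ClassPrototypes(
            vectors=np.stack([random_bipolar(512, rng) for _ in range(5)]),
            classes=("rest", "fist", "raise", "lower", "open"),
        )
        for c in range(5):
            assert classify(protos.vectors[c], protos) == c
        assert classify(-protos.vectors[0].astype(float), protos) != 0

    def test_full_precision_query_beats_bipolarized_at_low_snr(self, ncc_model):
        enc, protos, grams, labels = ncc_model
        y = channel.awgn(grams[:500], -5.0, 1.0, rng=9)
        acc_full = np.mean(classify(y, protos) == labels[:500])
        acc_bip = np.mean(classify(y, protos, bipolarize_query=True) == labels[:500])
        assert acc_full >= acc_bip


class TestReconstruction:
    def test_noise_free_error_bounded_by_level_width(self):
        cim = make_cim(128, 8192, seed=4)
        rng = np.random.default_rng(10)
        frames = rng.random((30, 64))
        enc = NccEncoder(NccConfig(dim=8192, seed=4))
        x = enc.spatial(frames)
        rec = reconstruct_stream(x.astype(float), enc.cim, feedback="soft")
        assert np.abs(rec - frames).max() <= 1.0 / 128

    def test_uniform_level_one_frame(self):
        # all channels at level 1: interference is 63 rotated copies of one
        # vector, so cancellation (feedback) is what makes recovery exact
        enc = NccEncoder(NccConfig(dim=4096, seed=5))
        x = enc.spatial(np.zeros((1, 64)))
        rec = reconstruct_stream(x.astype(float), enc.cim, feedback="soft")
        assert np.allclose(rec, 0.5 / 128)

    def test_soft_feedback_beats_none_in_noise(self):
        enc = NccEncoder(NccConfig(dim=1024, seed=6))
        rng = np.random.default_rng(11)
        frames = rng.random((40, 64))
        x = enc.spatial(frames)
        y = channel.awgn(x, 5.0, 64.0, rng=12)
        err_none = mse_db(reconstruct_stream(y, enc.cim, feedback="none"), frames)
        err_soft = mse_db(reconstruct_stream(y, enc.cim, feedback="soft"), frames)
        assert err_soft < err_none


class TestMetrics:
    @pytest.mark.parametrize("d,expected", [(512, 4.375), (2048, 1.094), (2240, 1.0)])
    def test_throughput_values(self, d, expected):
        assert emg_throughput(d) == pytest.approx(expected, abs=5e-4)

    def test_mse_db_closed_forms(self):
        x = np.random.default_rng(13).random((10, 64))
        assert mse_db(x, x) == float("-inf")
        assert mse_db(x + 0.1, x) == pytest.approx(-20.0, abs=1e-9)
        with pytest.raises(ValueError):
            mse_db(np.empty(0), np.empty(0))


class TestModeEquivalence:
    def test_both_modes_share_one_spatial_encoder(self):
        """Classification n-grams and transmission vectors must be built from
        byte-identical CiM levels and channel rotations."""
        enc = NccEncoder(NccConfig(dim=2048, seed=7))
        frames = np.random.default_rng(14).random((5, 64))
        x_transmit = enc.spatial(frames)
        cim_direct = spatial_encode(quantize_features(frames), enc.cim)
        assert np.array_equal(x_transmit, cim_direct)
        g = enc.ngrams(frames)
        from hdmod.ncc import temporal_encode as te

        manual = te(list(x_transmit), enc.tie_breaker, enc.ngram_perms)
        assert np.array_equal(g[0], manual)
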