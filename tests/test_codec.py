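"""Integer HDM codec: bit mapping, encoding, AM search, decoder, quantizers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hdmod import channel
from hdmod.codec import (
    BlockIndexes,
    CodeConfig,
    Decoder,
    DecoderConfig,
    am_search,
    bits_to_indexes,
    decode,
    encode,
    indexes_to_bits,
    make_codebooks,
    quantize_fixed_point,
    quantize_readout,
    throughput,
)
from hdmod.core import derived_rng, rotate


def _bitstring(rng, k):
    return "".join("01"[b] for b in rng.integers(0, 2, size=k))


class TestBitIndexMapping:
    def test_worked_example(self, small_code):
        config = small_code[0]
        assert bits_to_indexes("0100100010", config) == BlockIndexes(q=2, r=17, s=-1)
        assert indexes_to_bits(BlockIndexes(2, 17, -1), config) == "0100100010"

    def test_all_zero_block(self, small_code):
        config = small_code[0]
        assert bits_to_indexes("0" * 10, config) == BlockIndexes(0, 0, -1)
        assert indexes_to_bits(BlockIndexes(0, 0, 1), config) == "0" * 9 + "1"

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 2**10 - 1))
    def test_roundtrip_exhaustive_small(self, value):
        config = CodeConfig(dim=64, im_size=8, n_superposed=1, seed=1)
        u = format(value, "010b")
        assert indexes_to_bits(bits_to_indexes(u, config), config) == u

    def test_out_of_range_rejected(self, small_code):
        config = small_code[0]
        with pytest.raises(ValueError):
            indexes_to_bits(BlockIndexes(8, 0, 1), config)
        with pytest.raises(ValueError):
            indexes_to_bits(BlockIndexes(0, 64, 1), config)
        with pytest.raises(ValueError):
            bits_to_indexes("01", config)


class TestThroughput:
    @pytest.mark.parametrize(
        "v,n,d,expected",
        [
            (7, 512, 512, 133 / 512),
            (9, 2048, 512, 189 / 512),
            (1, 64, 512, 16 / 512),
            (1, 2048, 512, 21 / 512),
        ],
    )
    def test_closed_form(self, v, n, d, expected):
        assert throughput(CodeConfig(dim=d, im_size=n, n_superposed=v)) == pytest.approx(expected)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CodeConfig(dim=100, im_size=8, n_superposed=1)
        with pytest.raises(ValueError):
            CodeConfig(dim=64, im_size=7, n_superposed=1)


class TestEncode:
    def test_single_block_matches_formula(self, small_code):
        config, im, perms, _ = small_code
        x = encode("0100100010", im, perms, config)
        assert np.array_equal(x, -rotate(im.vectors[2], 17))

    def test_parity_invariant(self, medium_code):
        config, im, perms, _ = medium_code
        rng = np.random.default_rng(0)
        x = encode(_bitstring(rng, config.n_bits), im, perms, config)
        assert np.all(np.abs(x) <= 3)
        assert np.all(x % 2 == 1)

    def test_length_mismatch_rejected(self, medium_code):
        config, im, perms, _ = medium_code
        with pytest.raises(ValueError):
            encode("01", im, perms, config)


class TestAmSearch:
    def test_exact_match(self, small_code):
        _, im, _, _ = small_code
        idx, conf = am_search(rotate(im.vectors[3], 5), im)
        assert idx == BlockIndexes(3, 5, 1)
        assert conf == pytest.approx(1.0)
        idx, conf = am_search(-rotate(im.vectors[3], 5), im)
        assert idx == BlockIndexes(3, 5, -1)

    def test_fft_matches_direct_scan(self, small_code):
        """The transform-based search must agree bit-exactly with the
        exhaustive (q, r) scan, including on integer-valued ties."""
        _, im, _, _ = small_code
        rng = np.random.default_rng(1)
        for _ in range(100):
            y = rng.normal(0, 1, size=64) + im.vectors[rng.integers(0, 8)]
            assert am_search(y, im, method="fft")[0] == am_search(y, im, method="direct")[0]
        for _ in range(50):  # integer queries force exact grid ties
            y = rng.integers(-3, 4, size=64)
            if not np.any(y):
                continue
            assert am_search(y, im, method="fft")[0] == am_search(y, im, method="direct")[0]


class TestDecoder:
    def test_noise_free_roundtrip_grid(self):
        """Exact recovery in the noise-free channel across (V, N) configs."""
        rng = np.random.default_rng(2)
        for v, n in [(1, 64), (3, 256), (7, 512), (9, 2048)]:
            config = CodeConfig(dim=512, im_size=n, n_superposed=v, seed=v)
            im, perms, _ = make_codebooks(config)
            dec = Decoder(im, perms, config)
            for _ in range(15):
                u = _bitstring(rng, config.n_bits)
                res = dec.decode(encode(u, im, perms, config).astype(float))
                assert res.bits == u
                assert res.converged

    def test_single_block_terminates_after_one_iteration(self, small_code):
        config, im, perms, _ = small_code
        rng = np.random.default_rng(3)
        u = _bitstring(rng, config.n_bits)
        y = channel.awgn(encode(u, im, perms, config), 5.0, 1.0, rng=1)
        res = decode(y, im, perms, config)
        assert res.iterations == 1

    def test_soft_feedback_confidence_clipped(self, medium_code):
        config, im, perms, _ = medium_code
        rng = np.random.default_rng(4)
        u = _bitstring(rng, config.n_bits)
        y = channel.awgn(encode(u, im, perms, config), 3.0, config.n_superposed, rng=2)
        res = decode(y, im, perms, config, DecoderConfig(feedback="soft"))
        assert res.iterations <= 10
        assert np.all(res.confidences >= 0)

    def test_high_snr_zero_errors(self):
        config = CodeConfig(dim=512, im_size=512, n_superposed=7, seed=6)
        im, perms, _ = make_codebooks(config)
        dec = Decoder(im, perms, config)
        rng = np.random.default_rng(5)
        noise = derived_rng(6, 4)
        for _ in range(20):
            u = _bitstring(rng, config.n_bits)
            y = channel.awgn(encode(u, im, perms, config), 20.0, 7, rng=noise)
            assert dec.decode(y).bits == u


class TestQuantizers:
    @pytest.mark.parametrize(
        "y,vmax,expected",
        [(0.4, 5, 1.0), (8.2, 5, 5.0), (-8.2, 5, -5.0), (2.0, 5, 1.0), (-2.0, 5, -1.0), (0.0, 5, 1.0)],
    )
    def test_readout_grid_points(self, y, vmax, expected):
        assert quantize_readout(np.array([y]), vmax)[0] == expected

    def test_readout_grid_preserves_noise_free_superposition(self):
        rng = np.random.default_rng(7)
        x = rng.integers(-5, 6, size=200)
        x = x + (x % 2 == 0)  # odd-parity values, as V=5 superpositions have
        assert np.array_equal(quantize_readout(x.astype(float), 5), x)

    @pytest.mark.parametrize(
        "x,m,q,expected",
        [(0.73, 4, 1, 0.5), (31.7, 4, 1, 15.5), (-31.7, 4, 1, -15.5), (0.75, 4, 1, 1.0), (0.25, 4, 1, 0.5)],
    )
    def test_fixed_point_examples(self, x, m, q, expected):
        assert quantize_fixed_point(np.array([x]), m, q)[0] == expected

    def test_fixed_point_feedback_scale_levels(self):
        scales = quantize_fixed_point(np.linspace(0, 1, 101), 4, 1)
        assert set(np.unique(scales)) == {0.0, 0.5, 1.0}

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-40, 40, allow_nan=False), st.integers(1, 6), st.integers(0, 4))
    def test_fixed_point_idempotent_and_bounded(self, x, m, q):
        once = quantize_fixed_point(np.array([x]), m, q)
        assert np.array_equal(once, quantize_fixed_point(once, m, q))
        assert abs(once[0]) <= 2**m - 2.0**-q
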