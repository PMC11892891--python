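import numpy as np
import pytest

from mxsqueeze.htransform import (
    CodecError,
    HcompBlob,
    HTransformPlane,
    decode_hcomp,
    encode_hcomp,
    fill_invalid,
    h_forward,
    h_inverse,
)


class TestTransform:
    def test_single_block_coefficients(self):
        t = h_forward(np.array([[1, 2], [3, 4]]))
        # h0 = 10, hy (column difference) = 2, hx (row difference) = 4, hc = 0
        assert t.coefficients[0, 0] == 10
        assert t.coefficients[0, 1] == 2
        assert t.coefficients[1, 0] == 4
        assert t.coefficients[1, 1] == 0

    def test_constant_plane_concentrates_in_dc(self):
        plane = np.full((8, 8), 7)
        t = h_forward(plane)
        assert t.coefficients[0, 0] == 7 * 64
        off_dc = t.coefficients.copy()
        off_dc[0, 0] = 0
        assert (off_dc == 0).all()

    @pytest.mark.parametrize("shape", [(64, 64), (37, 61), (1, 5), (100, 3), (128, 128)])
    def test_exact_inverse(self, shape):
        rng = np.random.default_rng(hash(shape) % 2**31)
        for _ in range(5):
            plane = rng.integers(-100_000, 100_000, shape)
            assert np.array_equal(h_inverse(h_forward(plane)), plane)

    def test_dc_only_reconstruction_is_blockwise_mean(self):
        rng = np.random.default_rng(3)
        plane = rng.integers(0, 1000, (8, 8))
        t = h_forward(plane)
        coeffs = np.zeros_like(t.coefficients)
        coeffs[0, 0] = t.coefficients[0, 0]
        recon = h_inverse(HTransformPlane(coeffs, t.n_levels, t.original_shape))
        # keeping only the DC term reproduces the global mean everywhere
        # (within the floor rounding of the integer inverse)
        assert np.all(np.abs(recon - plane.mean()) <= 1)

    def test_inconsistent_levels_raise(self):
        t = h_forward(np.ones((4, 4), int))
        with pytest.raises(CodecError):
            h_inverse(HTransformPlane(t.coefficients, 5, (4, 4)))


class TestCodec:
    @pytest.mark.parametrize("scale", [0, 1])
    @pytest.mark.parametrize("shape", [(64, 64), (37, 61), (5, 200)])
    def test_lossless_at_low_scale(self, scale, shape):
        rng = np.random.default_rng(11)
        plane = rng.integers(-5000, 50_000, shape)
        blob = encode_hcomp(plane, scale)
        assert np.array_equal(decode_hcomp(blob), plane)

    def test_constant_plane_exact_at_any_scale(self):
        plane = np.full((32, 32), 1234)
        for scale in (0, 4, 64):
            assert np.array_equal(decode_hcomp(encode_hcomp(plane, scale)), plane)

    def test_blob_bytes_round_trip(self):
        plane = np.arange(64 * 64).reshape(64, 64)
        blob = encode_hcomp(plane, 8)
        back = HcompBlob.from_bytes(blob.to_bytes())
        assert back.scale == 8 and back.original_shape == (64, 64)
        assert np.array_equal(decode_hcomp(back), decode_hcomp(blob))

    def test_corrupted_payload_raises(self):
        blob = encode_hcomp(np.arange(256).reshape(16, 16), 0)
        bad = HcompBlob(blob.scale, blob.payload[:3], blob.n_levels, blob.original_shape)
        with pytest.raises(CodecError):
            decode_hcomp(bad)

    def test_unknown_variant_rejected(self):
        blob = encode_hcomp(np.ones((4, 4), int), 0)
        blob.codec_variant_id = "xxxx"
        with pytest.raises(CodecError, match="variant"):
            decode_hcomp(blob)

    def test_monotone_size_and_error_over_scales(self):
        """Payload shrinks and RMS error grows as the scale coarsens."""
        rng = np.random.default_rng(5)
        plane = rng.poisson(40.0, (96, 96)).astype(np.int64)
        plane[40:46, 50:56] += rng.poisson(300.0, (6, 6))  # a bright feature
        sizes, errors = [], []
        for scale in (0, 4, 8, 16, 32, 64):
            blob = encode_hcomp(plane, scale)
            recon = decode_hcomp(blob)
            sizes.append(len(blob.to_bytes()))
            errors.append(float(np.sqrt(((recon - plane) ** 2).mean())))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(errors, errors[1:]))
        assert errors[0] == 0.0

    def test_quantization_error_bounded_per_coefficient(self):
        from mxsqueeze.htransform import _dequantize, _quantize

        rng = np.random.default_rng(6)
        coeffs = rng.integers(-10_000, 10_000, (32, 32))
        for scale in (4, 64):
            recon = _dequantize(_quantize(coeffs, scale), scale)
            delta = np.abs(recon - coeffs)
            assert delta[0, 0] == 0  # DC is exact
            assert delta.max() <= scale // 2

    def test_quantization_rounds_half_away_from_zero(self):
        from mxsqueeze.htransform import _quantize

        coeffs = np.array([[99, 8], [-8, 3]])  # [0,0] is DC, untouched
        q = _quantize(coeffs, 16)
        assert q[0, 0] == 99
        assert q[0, 1] == 1 and q[1, 0] == -1  # +/-8 -> +/-1 at scale 16
        assert q[1, 1] == 0

    def test_dc_preserved_so_total_counts_survive(self):
        rng = np.random.default_rng(7)
        plane = rng.poisson(30.0, (64, 64)).astype(np.int64)
        recon = decode_hcomp(encode_hcomp(plane, 64))
        # total counts change only through non-DC rounding, which cancels
        assert abs(recon.sum() - plane.sum()) / plane.sum() < 0.02


class TestMaskFilling:
    def test_fill_uses_neighbourhood_median(self):
        counts = np.full((10, 10), 50)
        counts[4, 4] = 0
        valid = np.ones((10, 10), bool)
        valid[4, 4] = False
        filled = fill_invalid(counts, valid)
        assert filled[4, 4] == 50

    def test_deep_gap_falls_back_to_global_median(self):
        counts = np.full((20, 20), 33)
        valid = np.ones((20, 20), bool)
        valid[5:15, :] = False  # 10-row gap: interior rows have no neighbours
        counts[~valid] = 0
        filled = fill_invalid(counts, valid)
        assert (filled[5:15, :] == 33).all()

    def test_all_valid_is_identity(self):
        counts = np.arange(16).reshape(4, 4)
        assert np.array_equal(fill_invalid(counts, np.ones((4, 4), bool)), counts)
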