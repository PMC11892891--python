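import numpy as np
import pytest

from mxsqueeze.core import DetectorGeometry, Frame, PipelineSpec, ScanMetadata
from mxsqueeze.metrics import (
    ImpactThresholds,
    compression_report,
    extract_profile,
    peak_impact,
    real_space_r,
    real_space_r_average,
    stack_impact,
)
from mxsqueeze.pipeline import compress_pipeline, decompress_pipeline
from mxsqueeze.synth import PeakSpec, SceneConfig, render_stack


class TestCompressionReport:
    def test_byteoffset_only_ecr_near_one(self, tiny_stack):
        cstack = compress_pipeline(tiny_stack, PipelineSpec.parse("byteoffset"))
        rep = compression_report(tiny_stack, cstack)
        # numerator and denominator measure the same stream; the mask and
        # header add a small container overhead on tiny frames
        assert rep.ecr == pytest.approx(1.0, rel=0.35)

    def test_ecr_times_baseline_is_total(self, desk_small):
        stack, _ = desk_small
        cstack = compress_pipeline(stack, PipelineSpec.parse("bin2,sum2,hcomp:16"))
        rep = compression_report(stack, cstack)
        assert rep.ecr * rep.baseline_ratio == pytest.approx(rep.total_ratio, rel=1e-12)

    def test_desk_small_baseline_at_least_two(self, desk_small):
        stack, _ = desk_small
        cstack = compress_pipeline(stack, PipelineSpec.parse("byteoffset"))
        rep = compression_report(stack, cstack)
        assert rep.baseline_ratio >= 2.0

    def test_reduction_multiplies_total_ratio(self, desk_small):
        stack, _ = desk_small
        plain = compression_report(
            stack, compress_pipeline(stack, PipelineSpec.parse("byteoffset"))
        )
        reduced = compression_report(
            stack, compress_pipeline(stack, PipelineSpec.parse("bin2,sum2,byteoffset"))
        )
        # x8 sample reduction, discounted by byte-offset efficiency change
        assert reduced.total_ratio / plain.total_ratio >= 4.0

    def test_sizes_positive(self, tiny_stack):
        rep = compression_report(
            tiny_stack, compress_pipeline(tiny_stack, PipelineSpec.parse("hcomp:4"))
        )
        assert rep.raw_bytes > 0 and rep.byte_offset_bytes > 0 and rep.lossy_bytes > 0


class TestExtractProfile:
    def flat_frame(self, value=20):
        return Frame(np.full((32, 64), value, np.int32), np.ones((32, 64), bool))

    def test_flat_background_gives_constant_profile(self):
        prof = extract_profile(self.flat_frame(), (16, 32), n_rows=6, half_width=10)
        assert prof.values.shape == (21,)
        assert np.allclose(prof.values, 20.0)

    def test_symmetric_peak_gives_symmetric_profile(self):
        frame = self.flat_frame(0)
        rr, cc = np.mgrid[0:32, 0:64]
        lam = 500.0 * np.exp(-((rr - 16.0) ** 2 + (cc - 32.0) ** 2) / (2 * 2.0**2))
        frame.counts = np.round(lam).astype(np.int32)  # noiseless lambda plane
        prof = extract_profile(frame, (16, 32), n_rows=7, half_width=8)
        assert np.allclose(prof.values, prof.values[::-1], atol=0.5)

    def test_gaussian_peak_profile_matches_closed_form(self):
        b, h, sigma = 10.0, 200.0, 2.0
        frame = self.flat_frame(0)
        rr, cc = np.mgrid[0:32, 0:64]
        lam = b + h * np.exp(-((rr - 16.0) ** 2 + (cc - 32.0) ** 2) / (2 * sigma**2))
        frame.counts = lam.astype(np.int32)  # truncation noise < 1 count
        prof = extract_profile(frame, (16, 32), n_rows=6, half_width=6)
        rows = np.arange(16 - 2, 16 + 4)  # the 6 averaged rows
        row_factor = np.mean(np.exp(-((rows - 16.0) ** 2) / (2 * sigma**2)))
        expected_center = b + h * row_factor
        assert prof.values[6] == pytest.approx(expected_center, abs=1.0)

    def test_fully_invalid_column_flagged_nan(self):
        frame = self.flat_frame()
        frame.valid[:, 30] = False
        prof = extract_profile(frame, (16, 32), n_rows=6, half_width=5)
        assert np.isnan(prof.values[3])  # column 30
        assert np.isfinite(prof.values[[0, 1, 2, 4]]).all()

    def test_window_must_fit(self):
        with pytest.raises(ValueError):
            extract_profile(self.flat_frame(), (2, 2), n_rows=6, half_width=10)


def _single_peak_frames(seed=3, intensity=2000.0, base=20.0):
    geometry = DetectorGeometry(64, 64, 0.075, 32, 32, 100, 1.0)
    peak = PeakSpec(30.0, 34.0, 0.1, intensity, 1.5, 0.05)
    config = SceneConfig(geometry, ScanMetadata(0.0, 0.2, 1), base, 1e9, (peak,), seed)
    stack, truth = render_stack(config)
    return stack[0], peak


class TestPeakImpact:
    def test_identity_is_preserved_with_zero_deltas(self):
        frame, peak = _single_peak_frames()
        report = peak_impact(frame, frame, peak)
        assert report.classification == "preserved"
        assert report.after.intensity == report.before.intensity
        assert report.shape_correlation == 1.0

    def test_peak_replaced_by_background_is_lost(self):
        frame, peak = _single_peak_frames()
        test = frame.copy()
        rng = np.random.default_rng(9)
        rr, cc = np.mgrid[0:64, 0:64]
        window = (rr - peak.row) ** 2 + (cc - peak.col) ** 2 <= (3 * peak.sigma_px) ** 2
        test.counts[window] = rng.poisson(20.0, int(window.sum()))
        assert peak_impact(frame, test, peak).classification == "lost"

    def test_doubled_peak_is_boosted(self):
        frame, peak = _single_peak_frames()
        test = frame.copy()
        rr, cc = np.mgrid[0:64, 0:64]
        window = (rr - peak.row) ** 2 + (cc - peak.col) ** 2 <= (3 * peak.sigma_px) ** 2
        test.counts[window] = (test.counts[window] * 2).astype(np.int32)
        assert peak_impact(frame, test, peak).classification == "boosted"

    def test_constant_offset_invariance(self):
        frame, peak = _single_peak_frames()
        noisy = frame.copy()
        rng = np.random.default_rng(4)
        noisy.counts = noisy.counts + rng.integers(-2, 3, noisy.counts.shape).astype(np.int32)
        base_report = peak_impact(frame, noisy, peak)
        shifted_ref = frame.copy()
        shifted_ref.counts = shifted_ref.counts + 100
        shifted_test = noisy.copy()
        shifted_test.counts = shifted_test.counts + 100
        shift_report = peak_impact(shifted_ref, shifted_test, peak)
        assert shift_report.classification == base_report.classification
        assert shift_report.before.intensity == pytest.approx(
            base_report.before.intensity, abs=1e-6
        )

    def test_fully_invalid_annulus_raises(self):
        frame, peak = _single_peak_frames()
        frame.valid[:] = False
        with pytest.raises(ValueError, match="annulus"):
            peak_impact(frame, frame, peak)


class TestStackImpact:
    def test_identity_stack_all_preserved(self):
        from mxsqueeze.synth import hcomp_benchmark_scene

        stack, truth = render_stack(hcomp_benchmark_scene(seed=5))
        summary = stack_impact(stack, stack, truth)
        assert summary.fractions["preserved"] == 1.0
        assert np.allclose(summary.background_variance_ratio, 1.0)
        assert not summary.over_compressed

    def test_mismatched_stacks_rejected(self, tiny_stack, desk_small):
        stack, truth = desk_small
        with pytest.raises(ValueError, match="aligned"):
            stack_impact(stack, tiny_stack, truth)

    def test_over_compression_flag_from_lost_fraction(self):
        from mxsqueeze.synth import hcomp_benchmark_scene

        stack, truth = render_stack(hcomp_benchmark_scene(seed=11))
        rec = decompress_pipeline(compress_pipeline(stack, PipelineSpec.parse("hcomp:64")))
        summary = stack_impact(
            stack, rec, truth, ImpactThresholds(lost_fraction_bound=0.05)
        )
        assert summary.fractions["lost"] > 0.05
        assert summary.over_compressed


class TestRealSpaceR:
    def test_identical_grids_zero_in_both_modes(self):
        rng = np.random.default_rng(0)
        grid = rng.normal(size=(6, 6, 6))
        assert real_space_r(grid, grid, "total_density") == 0.0
        assert real_space_r(grid, grid, "variance") == 0.0

    def test_constant_offset_variance_closed_form(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(5, 5, 5))
        c = 0.7
        expected = ref.size * c**2 / ((ref - ref.mean()) ** 2).sum()
        assert real_space_r(ref, ref + c, "variance") == pytest.approx(expected)

    def test_reversed_grid_brute_force(self):
        ref = np.arange(8, dtype=float).reshape(2, 2, 2)
        test = ref.ravel()[::-1].reshape(2, 2, 2)
        # brute force: sum|d|/sum|ref| and sum d^2 / sum (ref-mean)^2
        num_td = np.abs(ref - test).sum()  # |0-7|+|1-6|+... = 32
        assert num_td == 32.0
        assert real_space_r(ref, test, "total_density") == pytest.approx(32.0 / 28.0)
        num_v = ((ref - test) ** 2).sum()  # 49+25+9+1 twice = 168
        den_v = ((ref - 3.5) ** 2).sum()  # 42
        assert (num_v, den_v) == (168.0, 42.0)
        assert real_space_r(ref, test, "variance") == pytest.approx(4.0)
        assert real_space_r_average(ref, test) == pytest.approx(
            0.5 * (32.0 / 28.0 + 4.0)
        )

    def test_flat_reference_variance_mode_rejected(self):
        flat = np.ones((3, 3, 3))
        with pytest.raises(ZeroDivisionError):
            real_space_r(flat, flat + 1.0, "variance")

    def test_non_negative_and_zero_iff_equal(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(4, 4, 4))
        test = ref + rng.normal(scale=1e-3, size=ref.shape)
        r = real_space_r(ref, test, "variance")
        assert r > 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            real_space_r(np.zeros((2, 2, 2)), np.zeros((3, 2, 2)))
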