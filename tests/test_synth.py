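import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from mxsqueeze.core import DetectorGeometry, ScanMetadata, validate_stack
from mxsqueeze.synth import (
    PeakSpec,
    SceneConfig,
    hcomp_benchmark_scene,
    marginal_peak_scene,
    phi_mass,
    preset,
    render_stack,
)


def small_geometry(n=64, gaps=()):
    return DetectorGeometry(
        n_rows=n,
        n_cols=n,
        pixel_size=0.075,
        beam_center_row=n / 2,
        beam_center_col=n / 2,
        detector_distance=150.0,
        wavelength=1.0,
        gap_regions=gaps,
    )


class TestRendering:
    def test_background_only_poisson_mean(self):
        config = SceneConfig(
            geometry=small_geometry(512),
            scan=ScanMetadata(0.0, 0.2, 1, 0.1),
            background_base=12.0,
            background_decay_px=1e9,  # flat
            seed=5,
        )
        stack, _ = render_stack(config)
        counts = stack[0].counts[stack[0].valid]
        # sample mean of 512^2 Poisson(12) draws: 5 sigma band
        se = np.sqrt(12.0 / counts.size)
        assert abs(counts.mean() - 12.0) < 5 * se

    def test_narrow_rocking_curve_lands_on_one_frame(self):
        peak = PeakSpec(32, 32, phi_center=0.9, total_intensity=1e4,
                        sigma_px=1.5, sigma_phi=0.01)
        scan = ScanMetadata(0.0, 0.2, 10)
        mass = phi_mass(peak, scan)
        assert mass[4] / mass.sum() >= 0.99  # phi=0.9 lies in frame 4

    def test_phi_mass_matches_numeric_integral(self):
        """Ground-truth lambda against direct quadrature of the rocking curve."""
        peak = PeakSpec(20, 20, phi_center=1.3, total_intensity=1e4,
                        sigma_px=1.0, sigma_phi=0.25)
        scan = ScanMetadata(0.3, 0.2, 10)  # spans phi_center +/- 4 sigma_phi
        config = SceneConfig(small_geometry(), scan, 1.0, 1e9, (peak,), seed=0)
        _, truth = render_stack(config)
        for i in range(scan.n_frames):
            lo, hi = scan.phi_range(i)
            expected = peak.total_intensity * quad(
                lambda x: norm.pdf(x, 1.3, 0.25), lo, hi
            )[0]
            assert truth.lam[0, i] == pytest.approx(expected, rel=1e-6)
        total = peak.total_intensity * (
            norm.cdf(scan.osc_start + scan.total_rotation, 1.3, 0.25)
            - norm.cdf(scan.osc_start, 1.3, 0.25)
        )
        assert truth.lam[0].sum() == pytest.approx(total, rel=1e-4)

    def test_bit_identical_for_identical_config(self):
        config = hcomp_benchmark_scene(seed=3)
        a, _ = render_stack(config)
        b, _ = render_stack(config)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.counts, fb.counts)

    def test_different_seed_differs(self):
        a, _ = render_stack(marginal_peak_scene(seed=1))
        b, _ = render_stack(marginal_peak_scene(seed=2))
        assert not np.array_equal(a[0].counts, b[0].counts)

    def test_count_conservation_in_expectation(self):
        """Background-subtracted integrated signal matches the truth lambdas."""
        peak = PeakSpec(30.0, 30.0, 0.5, total_intensity=5e4, sigma_px=1.5, sigma_phi=0.08)
        config = SceneConfig(
            small_geometry(), ScanMetadata(0.0, 0.2, 5), 6.0, 1e9, (peak,), seed=21
        )
        stack, truth = render_stack(config)
        measured = 0.0
        window = np.zeros((64, 64), bool)
        rr, cc = np.mgrid[0:64, 0:64]
        window[(rr - 30) ** 2 + (cc - 30) ** 2 <= 8**2] = True
        for i, frame in enumerate(stack):
            measured += frame.counts[window].sum() - 6.0 * window.sum()
        total = truth.lam[0].sum()
        # Poisson MC error on the windowed sum over 5 frames
        mc_sigma = np.sqrt(total + 5 * 6.0 * window.sum())
        assert abs(measured - total) < 3 * mc_sigma

    def test_gap_pixels_invalid_and_zero(self):
        config = SceneConfig(
            small_geometry(gaps=((10, 14, 0, 64),)),
            ScanMetadata(0.0, 0.2, 2),
            10.0,
            1e9,
            seed=1,
        )
        stack, _ = render_stack(config)
        for frame in stack:
            assert not frame.valid[10:14].any()
            assert (frame.counts[10:14] == 0).all()
            assert (frame.counts[frame.valid] >= 0).all()

    def test_peak_in_gap_marked_occluded(self):
        peak = PeakSpec(12.0, 30.0, 0.1, 1e3, 1.0, 0.05)
        config = SceneConfig(
            small_geometry(gaps=((10, 14, 0, 64),)),
            ScanMetadata(0.0, 0.2, 2),
            5.0,
            1e9,
            (peak,),
            seed=1,
        )
        _, truth = render_stack(config)
        assert truth.occluded[0]


class TestPresets:
    def test_lysozyme_like_scan(self):
        config = preset("lysozyme-like")
        assert config.scan.n_frames == 1800
        assert config.scan.osc_width == pytest.approx(0.2)
        assert config.scan.total_rotation == pytest.approx(360.0)

    def test_rt_like_total_rotation(self):
        config = preset("rt-like")
        assert config.scan.n_frames == 1200
        assert config.scan.total_rotation == pytest.approx(240.0)

    def test_desk_small_renders_quickly(self):
        import time

        t0 = time.monotonic()
        stack, _ = render_stack(preset("desk-small", seed=7))
        assert time.monotonic() - t0 < 5.0
        assert len(stack) == 40 and stack.shape == (512, 512)
        assert validate_stack(stack) == []

    def test_unknown_preset_lists_options(self):
        with pytest.raises(ValueError, match="desk-small"):
            preset("nonexistent")


class TestGroundTruthReduction:
    def test_reduce_maps_coordinates_and_sums_lambda(self):
        _, truth = render_stack(hcomp_benchmark_scene(seed=2))
        reduced = truth.reduce(bin_n=2, sum_m=2)
        assert reduced.peaks[0].row == pytest.approx(truth.peaks[0].row / 2)
        assert reduced.peaks[0].sigma_px == pytest.approx(truth.peaks[0].sigma_px / 2)
        assert reduced.lam.shape[1] == truth.lam.shape[1] // 2
        assert reduced.lam[0, 0] == pytest.approx(truth.lam[0, 0] + truth.lam[0, 1])
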