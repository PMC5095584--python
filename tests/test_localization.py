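"""Spot detection, trace extraction, step detection and the 7-parameter fit."""

import numpy as np
import pytest

from flimp import localization as loc
from flimp.simulate import CameraModel, EmitterPairTruth, render_spot_stack
from tests.conftest import make_close_pair


class TestDetectSpots:
    def test_blank_frame_empty(self):
        assert len(loc.detect_spots(np.zeros((32, 32)))) == 0

    def test_recovers_well_separated_spots(self, camera):
        rng = np.random.default_rng(0)
        frame = rng.poisson(10.0, size=(64, 64)).astype(float)
        centers = [(10, 10), (10, 50), (32, 32), (50, 12), (54, 54)]
        from flimp.simulate import integrated_gaussian
        for r, c in centers:
            frame += 3000.0 * integrated_gaussian((64, 64), c, r, 2.7)
        found = loc.detect_spots(frame, min_snr=5, min_sep_px=5)
        assert len(found) == 5
        for r, c in centers:
            assert min(abs(fr - r) + abs(fc - c) for fr, fc in found) <= 2

    def test_nearby_spots_suppressed(self):
        from flimp.simulate import integrated_gaussian
        frame = 3000.0 * (integrated_gaussian((32, 32), 15, 15, 2.7)
                          + integrated_gaussian((32, 32), 16, 15, 2.7))
        found = loc.detect_spots(frame, min_snr=5, min_sep_px=5)
        assert len(found) == 1


class TestExtractTrace:
    def test_flat_noiseless_trace(self, pair_truth, camera):
        stack = render_spot_stack(pair_truth, camera, seed=0, noise=False)
        tr = loc.extract_trace(stack, (7, 7), radius_px=6)
        # constant while both emitters are alive
        first = tr.intensities[0]
        assert np.allclose(tr.intensities[:12], first, rtol=1e-9)

    def test_trace_drops_at_bleach_frames(self, pair_truth, camera):
        stack = render_spot_stack(pair_truth, camera, seed=0, noise=False)
        tr = loc.extract_trace(stack, (7, 7), radius_px=6)
        b1, b2 = pair_truth.bleach_frames
        assert tr.intensities[b1] < 0.75 * tr.intensities[b1 - 1]
        assert tr.intensities[b2] == pytest.approx(0.0, abs=1e-6)

    def test_all_zero_stack(self):
        tr = loc.extract_trace(np.zeros((12, 15, 15)), (7, 7), radius_px=5)
        assert np.allclose(tr.intensities, 0.0)

    def test_edge_spot_rejected(self):
        with pytest.raises(ValueError):
            loc.extract_trace(np.zeros((5, 15, 15)), (1, 7), radius_px=5)


class TestDetectSteps:
    @staticmethod
    def _trace(levels, seg_len=15, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        y = np.concatenate([np.full(seg_len, lv) for lv in levels])
        if noise_sd:
            y = y + rng.normal(0, noise_sd, y.size)
        return loc.IntensityTrace("t", np.arange(y.size), y,
                                  np.zeros((y.size, 2)))

    def test_exact_change_points_on_clean_trace(self):
        seg = loc.detect_steps(self._trace([1000, 500, 0], noise_sd=1.0))
        assert seg.two_emitter == (0, 15)
        assert seg.one_emitter == (15, 30)
        assert seg.zero == (30, 45)
        assert seg.n_steps == 2

    def test_three_level_trace_keeps_lowest_two(self):
        seg = loc.detect_steps(
            self._trace([1500, 1000, 500, 0], noise_sd=1.0)
        )
        assert seg.levels[0] == pytest.approx(1000, rel=0.05)
        assert seg.levels[1] == pytest.approx(500, rel=0.05)
        assert seg.two_emitter == (15, 30)
        assert seg.one_emitter == (30, 45)
        assert seg.n_steps == 3

    def test_flat_trace_rejected(self):
        with pytest.raises(loc.TraceRejected):
            loc.detect_steps(self._trace([1000], seg_len=40, noise_sd=1.0))

    def test_single_step_rejected(self):
        with pytest.raises(loc.TraceRejected):
            loc.detect_steps(self._trace([1000, 0], noise_sd=1.0))

    def test_no_decay_to_zero_rejected(self):
        with pytest.raises(loc.TraceRejected):
            loc.detect_steps(self._trace([1500, 1000, 500], noise_sd=1.0))

    def test_short_trace_error(self):
        with pytest.raises(ValueError):
            loc.detect_steps(self._trace([10, 0], seg_len=4))


class TestTwoEmitterFit:
    def test_noiseless_recovery_exact(self, pair_truth, camera, noiseless_stack):
        tr = loc.extract_trace(noiseless_stack, (7, 7), radius_px=6)
        seg = loc.detect_steps(tr)
        fit = loc.fit_two_emitters(noiseless_stack, seg, camera, n_boot=0)
        assert fit.converged and not fit.degenerate
        # emitter 2 is the survivor (bleaches at 25): truth (400, 700)
        assert fit.x2_nm == pytest.approx(400.0, abs=1e-3 * 100)
        assert fit.x1_nm == pytest.approx(1000.0, abs=1e-3 * 100)
        assert fit.y1_nm == pytest.approx(700.0, abs=1e-3 * 100)
        assert fit.fwhm_nm == pytest.approx(300.0, rel=1e-4)
        assert fit.separation_nm == pytest.approx(600.0, abs=0.1)

    def test_noiseless_residuals_numerically_zero(
        self, pair_truth, camera, noiseless_stack
    ):
        tr = loc.extract_trace(noiseless_stack, (7, 7), radius_px=6)
        seg = loc.detect_steps(tr)
        fit = loc.fit_two_emitters(noiseless_stack, seg, camera, n_boot=0)
        from flimp.localization import _two_emitter_residuals
        px = camera.pixel_size_nm
        theta = np.array([fit.x1_nm / px, fit.y1_nm / px, fit.I1,
                          fit.x2_nm / px, fit.y2_nm / px, fit.I2,
                          fit.fwhm_nm / px])
        a0, a1 = seg.two_emitter
        b0, b1 = seg.one_emitter
        bg = camera.background_photons_per_px
        A = noiseless_stack[a0:a1].mean(axis=0) - bg
        B = noiseless_stack[b0:b1].mean(axis=0) - bg
        rows = np.arange(15.0)
        resid, _ = _two_emitter_residuals(theta, A, B, rows, rows)
        assert np.abs(resid).max() < 1e-6 * A.max()

    def test_overlapping_emitters_flagged_degenerate(self, camera):
        truth = EmitterPairTruth(
            positions_nm=np.array([[700.5, 700.0], [699.5, 700.0]]),  # 0.01 px
            photons_per_frame=5000.0, bleach_frames=(12, 25),
        )
        stack = render_spot_stack(truth, camera, seed=0, noise=False)
        tr = loc.extract_trace(stack, (7, 7), radius_px=6)
        seg = loc.detect_steps(tr)
        fit = loc.fit_two_emitters(stack, seg, camera, n_boot=0)
        assert fit.degenerate
        with pytest.raises(ValueError):
            loc.measured_separation(fit)

    def test_centroid_shift_consistency(self, camera):
        """The one-emitter-segment centroid agrees with the fitted survivor
        position within its localization error in >= 95% of runs."""
        rng = np.random.default_rng(11)
        n_ok, n_tot = 0, 0
        for _ in range(60):
            truth = make_close_pair(19.6, rng)
            stack = render_spot_stack(truth, camera,
                                      seed=int(rng.integers(2**31)))
            try:
                tr = loc.extract_trace(stack, (7, 7), radius_px=6)
                seg = loc.detect_steps(tr)
                fit = loc.fit_two_emitters(stack, seg, camera, n_boot=40,
                                           seed=int(rng.integers(2**31)))
            except loc.TraceRejected:
                continue
            if not fit.converged or fit.degenerate:
                continue
            b0, b1 = seg.one_emitter
            cents = tr.centroids_px[b0:b1]
            cx, cy = np.nanmean(cents, axis=0) * camera.pixel_size_nm
            err = np.hypot(cx - fit.x2_nm, cy - fit.y2_nm)
            # 3 sigma covers ~99% of a 2D Gaussian radius; centroid noise
            # adds a little on top of the fit error
            n_ok += err < 3.0 * fit.sigma2_nm + 1.0
            n_tot += 1
        assert n_tot >= 40
        assert n_ok / n_tot >= 0.95

    def test_separation_recovery_median_within_1nm(self, camera):
        """Median measured separation over many synthetic tetramer-like
        complexes is within 1 nm of the 19.6 nm truth."""
        rng = np.random.default_rng(21)
        ds = []
        for _ in range(120):
            truth = make_close_pair(19.6, rng)
            stack = render_spot_stack(truth, camera,
                                      seed=int(rng.integers(2**31)))
            try:
                fit = loc.measure_complex(stack, camera, n_boot=0)
            except loc.TraceRejected:
                continue
            if fit.converged and not fit.degenerate:
                ds.append(fit.separation_nm)
        assert len(ds) >= 100
        assert abs(np.median(ds) - 19.6) < 1.0


class TestMeasuredSeparation:
    @staticmethod
    def _fit(x1, y1, x2, y2, s1=1.0, s2=1.0):
        return loc.TwoEmitterFit(
            x1_nm=x1, y1_nm=y1, x2_nm=x2, y2_nm=y2, I1=1, I2=1,
            fwhm_nm=270, sigma1_nm=s1, sigma2_nm=s2,
            sigma_pair_nm=np.nan,  # falls back to the independent combination
            converged=True, degenerate=False, n_boot=0,
        )

    def test_three_four_five(self):
        d, sig = loc.measured_separation(self._fit(0, 0, 3, 4))
        assert d == pytest.approx(5.0)
        assert sig == pytest.approx(np.sqrt(2.0))

    def test_coincident_emitters(self):
        d, _ = loc.measured_separation(self._fit(5, 5, 5, 5))
        assert d == 0.0
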