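"""Centroid trajectories, filtering, spectra, alignment, grading, 3-D errors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

import fluorotrack as ft

from conftest import random_geometry


class TestCentroid:
    def test_single_pixel(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[20, 10] = True
        assert ft.centroid(mask) == (10.0, 20.0)

    def test_rectangle_center(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:15, 8:20] = True
        assert ft.centroid(mask) == ((8 + 19) / 2.0, (5 + 14) / 2.0)

    def test_matches_index_enumeration(self):
        rng = np.random.default_rng(0)
        mask = rng.random((64, 64)) < 0.3
        xs, ys = [], []
        for i in range(64):
            for j in range(64):
                if mask[i, j]:
                    ys.append(i)
                    xs.append(j)
        assert ft.centroid(mask) == pytest.approx((np.mean(xs), np.mean(ys)))

    def test_empty_mask_signals(self):
        with pytest.raises(ft.EmptyMaskError):
            ft.centroid(np.zeros((8, 8), dtype=bool))


class TestExtractTrajectory:
    @staticmethod
    def _dot_mask(x, y, shape=(32, 32)):
        mask = np.zeros(shape, dtype=bool)
        mask[y, x] = True
        return mask

    def test_timestamps_follow_frame_rate(self):
        masks = [self._dot_mask(5, 5)] * 9
        traj = ft.extract_trajectory(masks, fs=30.0)
        assert len(traj) == 9
        assert np.allclose(traj.t, np.arange(9) / 30.0)

    def test_static_masks_give_constant_trajectory(self):
        traj = ft.extract_trajectory([self._dot_mask(7, 3)] * 5)
        assert np.ptp(traj.points, axis=0).max() == 0.0

    def test_empty_middle_frame_carried_forward_with_flag(self):
        masks = [self._dot_mask(5, 5), np.zeros((32, 32), bool), self._dot_mask(9, 9)]
        traj = ft.extract_trajectory(masks)
        assert tuple(traj.points[1]) == (5.0, 5.0)
        assert traj.flags.tolist() == [False, True, False]

    def test_empty_first_frame_rejected(self):
        with pytest.raises(ft.EmptyMaskError, match="first frame"):
            ft.extract_trajectory([np.zeros((8, 8), bool)])


class TestLowpass:
    def test_constant_trajectory_unchanged(self):
        traj = ft.Trajectory2D(np.full((60, 2), 17.0), fs=30.0)
        out = ft.lowpass(traj, ft.FilterSpec())
        assert np.allclose(out.points, 17.0)

    def test_passband_sine_passes_with_zero_lag(self):
        t = np.arange(0, 20.0, 1 / 30.0)
        x = np.sin(2 * np.pi * 1.0 * t)
        traj = ft.Trajectory2D(np.column_stack([x, x]), fs=30.0)
        out = ft.lowpass(traj, ft.FilterSpec(fc=8.0, fs=30.0))
        y = out.points[:, 0]
        core = slice(30, -30)
        assert np.ptp(y[core]) >= 0.99 * np.ptp(x[core])
        xc = np.correlate(x - x.mean(), y - y.mean(), mode="full")
        assert np.argmax(xc) == len(x) - 1  # zero lag

    def test_stopband_attenuation_matches_squared_design_response(self):
        # forward-backward filtering squares the designed magnitude response
        t = np.arange(0, 10.0, 1 / 30.0)
        x = np.sin(2 * np.pi * 14.0 * t)
        traj = ft.Trajectory2D(np.column_stack([x, np.zeros_like(x)]), fs=30.0)
        out = ft.lowpass(traj, ft.FilterSpec(fc=8.0, fs=30.0))
        y = out.points[30:-30, 0]  # discard 1 s at each edge
        tt = t[30:-30]
        # synchronous demodulation at 14 Hz rejects residual edge transients,
        # which dominate plain RMS at -150 dB attenuation
        measured = 2.0 * np.abs(np.mean(y * np.exp(-2j * np.pi * 14.0 * tt)))
        b, a = ft.FilterSpec(fc=8.0, fs=30.0).coefficients()
        _, h = signal.freqz(b, a, worN=[2 * np.pi * 14.0 / 30.0])
        expected = np.abs(h[0]) ** 2
        assert measured == pytest.approx(expected, rel=0.05)

    def test_zero_phase_on_band_limited_mixture(self):
        t = np.arange(0, 30.0, 1 / 30.0)
        x = np.sin(2 * np.pi * 0.33 * t) + 0.4 * np.sin(2 * np.pi * 1.1 * t + 0.7)
        traj = ft.Trajectory2D(np.column_stack([x, x]), fs=30.0)
        y = ft.lowpass(traj).points[:, 0]
        xc = np.correlate(x - x.mean(), y - y.mean(), mode="full")
        assert np.argmax(xc) == len(x) - 1

    def test_filtering_is_invariant_to_prior_alignment(self):
        # both are linear and constant offsets pass the filter at DC gain 1,
        # so the final aligned trajectory is order-independent
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(90, 2)).cumsum(axis=0)
        ref = ft.Trajectory2D(rng.normal(size=(90, 2)), fs=30.0)
        traj = ft.Trajectory2D(pts, fs=30.0)
        ab = ft.align_to_reference(ft.lowpass(ft.align_to_reference(traj, ref)), ref)
        ba = ft.align_to_reference(ft.lowpass(traj), ref)
        assert np.abs(ab.points - ba.points).max() < 1e-9

    def test_invalid_cutoff_and_short_input_rejected(self):
        with pytest.raises(ValueError):
            ft.FilterSpec(fc=15.0, fs=30.0)
        with pytest.raises(ValueError, match="too short"):
            ft.lowpass(ft.Trajectory2D(np.zeros((10, 2)), fs=30.0), ft.FilterSpec())


class TestAmplitudeSpectrum:
    def test_constant_signal_has_empty_spectrum(self):
        traj = ft.Trajectory2D(np.full((64, 2), 3.0), fs=30.0)
        _, spec = ft.amplitude_spectrum(traj)
        assert np.allclose(spec, 0.0)

    def test_breathing_rate_peak_at_one_third_hertz(self):
        model = ft.MotionModel(rate_bpm=20.0)
        t = np.arange(0, 60.0, 1 / 30.0)
        disp = ft.respiratory_displacement(model, t)
        traj = ft.Trajectory2D(disp[:, [1, 2]], fs=30.0)
        assert round(ft.peak_frequency(traj), 2) == 0.33

    def test_parseval_energy_conservation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(301, 2))
        traj = ft.Trajectory2D(x, fs=30.0)
        freqs, spec = ft.amplitude_spectrum(traj)
        # odd length: no Nyquist bin; variance = sum A_k^2 / 2 (k >= 1)
        energy = (spec[1:] ** 2).sum(axis=0) / 2.0
        var = ((x - x.mean(axis=0)) ** 2).mean(axis=0)
        assert np.allclose(energy, var, rtol=1e-9)


class TestAlignToReference:
    def test_constant_offset_cancels_exactly(self):
        rng = np.random.default_rng(3)
        ref = ft.Trajectory2D(rng.normal(size=(40, 2)), fs=30.0)
        traj = ft.Trajectory2D(ref.points + np.array([5.0, 7.0]), fs=30.0)
        aligned = ft.align_to_reference(traj, ref)
        assert np.allclose(aligned.points, ref.points)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_direct_formula_and_mean_identity(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 10, size=(25, 2))
        ref_pts = rng.normal(0, 10, size=(25, 2))
        aligned = ft.align_to_reference(
            ft.Trajectory2D(pts, fs=30.0), ft.Trajectory2D(ref_pts, fs=30.0)
        ).points
        direct = pts - pts.mean(axis=0) + ref_pts.mean(axis=0)
        assert np.allclose(aligned, direct)
        assert np.allclose(aligned.mean(axis=0), ref_pts.mean(axis=0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ft.align_to_reference(
                ft.Trajectory2D(np.zeros((4, 2))), ft.Trajectory2D(np.zeros((5, 2)))
            )


class TestRmseGrade:
    def test_identical_trajectories_are_excellent(self):
        pts = np.random.default_rng(4).normal(size=(30, 2))
        report = ft.rmse_grade(ft.Trajectory2D(pts), ft.Trajectory2D(pts.copy()))
        assert report.e == 0.0
        assert report.grade == "Excellent"

    def test_sine_deviation_rmse_is_amplitude_over_sqrt2(self):
        n, cycles, amp = 300, 5, 4.0
        t = np.arange(n)
        dev = amp * np.sin(2 * np.pi * cycles * t / n)
        ref = ft.Trajectory2D(np.full((n, 2), 10.0))
        traj = ft.Trajectory2D(np.column_stack([10.0 + dev, np.full(n, 10.0)]))
        report = ft.rmse_grade(traj, ref)
        assert report.rmse_x == pytest.approx(amp / np.sqrt(2), rel=1e-9)
        assert report.e == report.rmse_x

    @pytest.mark.parametrize(
        "e,grade",
        [(0.0, "Excellent"), (2.999, "Excellent"), (3.0, "High"), (7.999, "High"),
         (8.0, "Moderate"), (12.999, "Moderate"), (13.0, "Low"), (40.0, "Low")],
    )
    def test_grade_boundaries(self, e, grade):
        assert ft.trajectory.grade_for_error(e) == grade

    def test_permutation_invariance_and_monotonicity(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(50, 2))
        traj = ref + rng.normal(0, 0.5, size=(50, 2))
        base = ft.rmse_grade(ft.Trajectory2D(traj), ft.Trajectory2D(ref))
        perm = rng.permutation(50)
        shuffled = ft.rmse_grade(ft.Trajectory2D(traj[perm]), ft.Trajectory2D(ref[perm]))
        assert shuffled.e == pytest.approx(base.e)
        worse = traj.copy()
        worse[10, 0] += 5.0
        assert ft.rmse_grade(ft.Trajectory2D(worse), ft.Trajectory2D(ref)).rmse_x > base.rmse_x


class TestTrajectory3D:
    def test_projected_path_round_trip(self):
        rng = np.random.default_rng(6)
        ga, gb = random_geometry(rng), random_geometry(rng)
        path = rng.uniform(-20, 20, (15, 3))
        pa = np.array([ft.project_point(ga, p) for p in path])
        pb = np.array([ft.project_point(gb, p) for p in path])
        rec = ft.trajectory_3d(ft.Trajectory2D(pa), ft.Trajectory2D(pb), ga, gb)
        assert np.abs(rec.points - path).max() < 1e-6
        assert np.all(rec.residuals < 1e-6)

    def test_static_pair_gives_constant_path(self, stereo_geoms):
        ga, gb = stereo_geoms
        pa = ft.project_point(ga, (3.0, -1.0, 2.0))
        pb = ft.project_point(gb, (3.0, -1.0, 2.0))
        rec = ft.trajectory_3d(
            ft.Trajectory2D(np.tile(pa, (6, 1))), ft.Trajectory2D(np.tile(pb, (6, 1))), ga, gb
        )
        assert np.ptp(rec.points, axis=0).max() < 1e-9

    def test_length_mismatch_rejected(self, stereo_geoms):
        with pytest.raises(ValueError):
            ft.trajectory_3d(
                ft.Trajectory2D(np.zeros((4, 2))), ft.Trajectory2D(np.zeros((5, 2))),
                *stereo_geoms,
            )


class TestErrorStats3D:
    def test_identical_paths_are_error_free(self):
        pts = np.random.default_rng(7).normal(size=(20, 3))
        stats = ft.error_stats_3d(ft.Trajectory3D(pts), ft.Trajectory3D(pts.copy()))
        assert np.all(stats.mean_abs == 0) and stats.median_euclidean == 0

    def test_constant_ap_offset(self):
        pts = np.random.default_rng(8).normal(size=(20, 3))
        shifted = pts + np.array([0.0, 0.0, 1.0])
        stats = ft.error_stats_3d(ft.Trajectory3D(shifted), ft.Trajectory3D(pts))
        assert stats.mean_abs == pytest.approx([0.0, 0.0, 1.0])
        assert stats.median_euclidean == pytest.approx(1.0)
        assert stats.iqr_euclidean == pytest.approx(0.0)

    def test_matches_per_frame_enumeration(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=(12, 3)), rng.normal(size=(12, 3))
        stats = ft.error_stats_3d(ft.Trajectory3D(a), ft.Trajectory3D(b))
        eucl = [np.sqrt(sum((a[k, i] - b[k, i]) ** 2 for i in range(3))) for k in range(12)]
        assert np.allclose(stats.euclidean, eucl)
        assert stats.median_euclidean == pytest.approx(np.median(eucl))
        for i in range(3):
            assert stats.mean_abs[i] == pytest.approx(np.mean(np.abs(a[:, i] - b[:, i])))


class TestMarkerTemplateTracking:
    @staticmethod
    def _dot_stack(offsets, shape=(64, 64), sigma=2.0):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        frames = []
        for dx, dy in offsets:
            frames.append(
                255.0 * np.exp(-((xx - 32 - dx) ** 2 + (yy - 32 - dy) ** 2) / (2 * sigma**2))
            )
        return np.stack(frames)

    def test_integer_shifts_recovered_exactly(self):
        offsets = [(0, 0), (2, 1), (4, -1), (6, -3), (5, 0)]
        stack = self._dot_stack(offsets)
        template = stack[0, 25:40, 25:40]  # 15x15 patch centered on the dot
        traj = ft.marker_track_template(stack, template, start=(32.0, 32.0))
        rec = traj.points - traj.points[0]
        assert np.allclose(rec, offsets, atol=1e-6)
        assert not traj.flags.any()

    def test_subpixel_shifts_recovered(self):
        offsets = [(0.0, 0.0), (0.5, 0.0), (1.0, 0.5), (1.5, 1.0)]
        stack = self._dot_stack(offsets)
        template = stack[0, 25:40, 25:40]
        traj = ft.marker_track_template(stack, template, start=(32.0, 32.0))
        rec = traj.points - traj.points[0]
        assert np.abs(rec - np.asarray(offsets)).max() < 0.2

    def test_template_larger_than_frame_rejected(self):
        with pytest.raises(ValueError, match="template"):
            ft.marker_track_template(
                np.zeros((2, 8, 8)), np.zeros((10, 10)), start=(4.0, 4.0)
            )
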