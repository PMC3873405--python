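"""Simulator contracts: motion-model physics, seeding, rendering."""

import numpy as np
import pytest

from saltatrack import (AcquisitionMeta, FilamentMap, GroundTruth, MotionClass,
                        MotionModelParams, generate_filament_map,
                        make_benchmark_dataset, render_movie, simulate_trajectory)
from saltatrack.synthetic_data import MotionModel, apportion_counts, _polyline_cumlen


def straight_filament(length_px=2000.0, y=50.0):
    return FilamentMap([np.array([[5.0, y], [5.0 + length_px, y]])])


class TestMotionModels:
    def test_confined_stays_within_radius(self, meta):
        params = MotionModelParams.confined(confinement_radius=300.0)
        radius_px = 300.0 / meta.pixel_size
        for seed in range(20):
            traj = simulate_trajectory(params, meta, start=(100.0, 100.0), seed=seed)
            r = np.hypot(*(traj.xy - [100.0, 100.0]).T)
            assert r.max() <= radius_px + 1e-9

    def test_zero_diffusion_brownian_is_static(self, meta):
        params = MotionModelParams(model=MotionModel.BROWNIAN, diffusion_coeff=0.0)
        traj = simulate_trajectory(params, meta, start=(30.0, 40.0), seed=1)
        assert np.allclose(traj.xy, [30.0, 40.0])

    def test_directed_constant_speed_matches_arclength_oracle(self, meta):
        """Pause-free, reversal-free, zero-spread transport at 700 nm/s must
        advance exactly 700 * frame_interval nm of arc per frame; on a
        straight filament the chord equals the arc."""
        fil = straight_filament()
        params = MotionModelParams.directed(track_id=0, run_speed_mean=700.0,
                                            run_speed_sd=0.0, pause_rate=0.0,
                                            reversal_prob=0.0)
        traj = simulate_trajectory(params, meta, start=(10.0, 50.0), seed=3,
                                   filaments=fil)
        step_nm = np.hypot(*np.diff(traj.xy, axis=0).T) * meta.pixel_size
        expected = 700.0 * meta.frame_interval
        assert np.allclose(step_nm, expected, rtol=1e-9)

    def test_directed_mean_speed_recovers_run_speed_within_2pct(self, meta):
        """Arc-length bookkeeping oracle: a pause-free run advances
        run_speed * frame_interval of arc per frame. On a long, gently
        curved filament (no end reflections within the movie, curvature
        radius >> per-frame advance) the chord speed recovers it."""
        x = np.linspace(0.0, 1800.0, 400)
        poly = np.column_stack([x + 10.0, 256.0 + 40.0 * np.sin(2 * np.pi * x / 600.0)])
        fil = FilamentMap([poly])
        cum = _polyline_cumlen(poly)
        start = poly[np.searchsorted(cum, cum[-1] / 2)]
        meta_wide = AcquisitionMeta(image_shape=(512, 2048), n_frames=meta.n_frames,
                                    frame_interval=meta.frame_interval,
                                    pixel_size=meta.pixel_size)
        params = MotionModelParams.directed(track_id=0, run_speed_mean=700.0,
                                            run_speed_sd=0.0, pause_rate=0.0,
                                            reversal_prob=0.0)
        speeds = []
        for seed in range(10):
            traj = simulate_trajectory(params, meta_wide, start=start, seed=seed,
                                       filaments=fil)
            v = np.hypot(*np.diff(traj.xy, axis=0).T) * meta.pixel_size / meta.frame_interval
            speeds.append(v.mean())
        assert np.mean(speeds) == pytest.approx(700.0, rel=0.02)

    def test_directed_positions_lie_on_polyline(self, meta):
        from saltatrack.synthetic_data import project_point_to_polyline
        fil = generate_filament_map(meta, 3, seed=2)
        params = MotionModelParams.directed(track_id=2)
        traj = simulate_trajectory(params, meta, start=fil[2][3], seed=8, filaments=fil)
        for p in traj.xy:
            _, d = project_point_to_polyline(fil[2], p)
            assert d < 1e-6

    def test_brownian_step_variance_matches_4dt(self, meta):
        """Ensemble MSD at lag 1 equals 4*D*t (closed form) within 10%."""
        D = 0.0017
        params = MotionModelParams.brownian(diffusion_coeff=D)
        steps = []
        for seed in range(500):
            traj = simulate_trajectory(params, meta, start=(256.0, 256.0), seed=seed)
            d_um = np.diff(traj.xy, axis=0) * meta.pixel_size / 1000.0
            steps.append(np.sum(d_um ** 2, axis=1))
        msd1 = np.mean(np.concatenate(steps))
        assert msd1 == pytest.approx(4.0 * D * meta.frame_interval, rel=0.10)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown motion model"):
            MotionModelParams(model="levy_flight")

    def test_start_outside_bounds_rejected(self, meta):
        with pytest.raises(ValueError, match="outside image bounds"):
            simulate_trajectory(MotionModelParams.brownian(), meta,
                                start=(9999.0, 10.0), seed=0)

    def test_seeded_reproducibility(self, meta):
        params = MotionModelParams.confined()
        a = simulate_trajectory(params, meta, start=(64.0, 64.0), seed=123)
        b = simulate_trajectory(params, meta, start=(64.0, 64.0), seed=123)
        assert np.array_equal(a.xy, b.xy)


class TestFilamentMap:
    def test_seeded_determinism_and_bounds(self, meta):
        a = generate_filament_map(meta, 5, seed=4)
        b = generate_filament_map(meta, 5, seed=4)
        assert len(a) == 5
        for pa, pb in zip(a.polylines, b.polylines):
            assert np.array_equal(pa, pb)
        h, w = meta.image_shape
        for poly in a.polylines:
            assert len(poly) >= 2
            assert (poly[:, 0] >= 0).all() and (poly[:, 0] < w).all()
            assert (poly[:, 1] >= 0).all() and (poly[:, 1] < h).all()

    def test_different_seeds_differ(self, meta):
        a = generate_filament_map(meta, 1, seed=1)
        b = generate_filament_map(meta, 1, seed=2)
        assert not (a[0].shape == b[0].shape and np.allclose(a[0], b[0]))

    def test_degenerate_polyline_rejected(self):
        with pytest.raises(ValueError):
            FilamentMap([np.array([[1.0, 1.0]])])
        with pytest.raises(ValueError):
            FilamentMap([np.array([[1.0, 1.0], [1.0, 1.0]])])


class TestRendering:
    def test_empty_truth_gives_pure_background(self, small_meta):
        truth = GroundTruth(trajectories=[], labels=[], params=[], seed=0)
        stack = render_movie(truth, small_meta, background=50.0, seed=1)
        assert stack.shape == (small_meta.n_frames, *small_meta.image_shape)
        assert abs(stack.mean() - 50.0) < 2.0
        # no structure: per-frame max should stay within Poisson range of bg
        assert stack.max() < 50.0 + 8 * np.sqrt(50.0)

    def test_noiseless_spot_peaks_at_ground_truth_pixel(self, small_meta):
        params = MotionModelParams(model=MotionModel.BROWNIAN, diffusion_coeff=0.0)
        traj = simulate_trajectory(params, small_meta, start=(40.0, 70.0), seed=0)
        traj.id = 0
        truth = GroundTruth(trajectories=[traj], labels=[MotionClass.P2_BROWNIAN],
                            params=[params], seed=0)
        stack = render_movie(truth, small_meta, noise=False)
        for frame in stack:
            iy, ix = np.unravel_index(np.argmax(frame), frame.shape)
            assert (ix, iy) == (40, 70)

    def test_snr_increases_with_photon_scale(self, small_meta):
        from saltatrack import detect_spots, measure_snr
        params = MotionModelParams(model=MotionModel.BROWNIAN, diffusion_coeff=0.0)
        traj = simulate_trajectory(params, small_meta, start=(60.0, 60.0), seed=0)
        traj.id = 0
        truth = GroundTruth(trajectories=[traj], labels=[MotionClass.P2_BROWNIAN],
                            params=[params], seed=0)
        snrs = []
        for scale in (40.0, 150.0, 600.0):
            frame = render_movie(truth, small_meta, photon_scale=scale, seed=2)[0]
            spots = detect_spots(frame, radius=3, percentile=0.005)
            assert spots, f"no detection at photon_scale={scale}"
            snrs.append(measure_snr(frame, spots[:1])[0])
        assert snrs[0] < snrs[1] < snrs[2]

    def test_stack_determinism(self, small_meta):
        stack1, _ = make_benchmark_dataset(n_trajectories=8, meta=small_meta, seed=3)
        stack2, _ = make_benchmark_dataset(n_trajectories=8, meta=small_meta, seed=3)
        assert np.array_equal(stack1, stack2)


class TestBenchmarkDataset:
    def test_apportionment_is_largest_remainder(self):
        assert apportion_counts((0.15, 0.41, 0.44), 100) == [15, 41, 44]
        assert apportion_counts((1.0, 0.0, 0.0), 10) == [10, 0, 0]
        # independent recount: totals always preserved
        for n in (1, 7, 33, 299):
            assert sum(apportion_counts((0.15, 0.41, 0.44), n)) == n

    def test_bad_mixture_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            apportion_counts((0.5, 0.2, 0.2), 10)

    def test_pure_mixture_all_confined(self, small_meta):
        _, truth = make_benchmark_dataset(mixture=(1.0, 0.0, 0.0), n_trajectories=10,
                                          meta=small_meta, seed=0, render=False)
        assert all(l is MotionClass.P1_RESTRICTED for l in truth.labels)

    def test_labels_params_trajectories_aligned(self, benchmark_300):
        t = benchmark_300
        assert len(t.trajectories) == len(t.labels) == len(t.params) == 300
        for label, p in zip(t.labels, t.params):
            assert p.motion_class is label

    def test_overcrowded_field_rejected(self):
        tiny = AcquisitionMeta(image_shape=(48, 48), n_frames=4)
        with pytest.raises(ValueError, match="could not place"):
            make_benchmark_dataset(n_trajectories=200, meta=tiny, seed=0,
                                   min_separation=12.0, render=False)

    def test_min_start_separation_honoured(self, rendered_benchmark):
        _, truth = rendered_benchmark
        starts = np.array([t.xy[0] for t in truth.trajectories])
        d = np.hypot(starts[:, None, 0] - starts[None, :, 0],
                     starts[:, None, 1] - starts[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 12.0 - 1e-9
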