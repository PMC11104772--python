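import numpy as np
import pytest

from ciliaflow import (
    AnalysisConfig,
    BeadDetection,
    BeadSimParams,
    BeadTrack,
    analyze_bead_movie,
    detect_beads,
    link_tracks,
    simulate_bead_movie,
    track_speed,
)
from ciliaflow.config import LinkingConfig


def gaussian_spot(shape, center, sigma=2.0, amplitude=1.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amplitude * np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2))


class TestDetectBeads:
    def test_single_spot_localized_within_half_pixel(self):
        frame = gaussian_spot((100, 120), (50.0, 70.0))
        dets = detect_beads(frame, sigma_px=2.0, threshold_rel=0.5)
        assert len(dets) == 1
        assert abs(dets[0].row - 50.0) < 0.5
        assert abs(dets[0].col - 70.0) < 0.5

    def test_blank_frame_gives_no_detections(self):
        assert detect_beads(np.zeros((50, 50))) == []

    def test_ten_known_spots_all_matched(self, rng):
        """Greedy matching oracle: each true center matched within 0.5 px."""
        shape = (200, 200)
        centers = [(20.0 + 40 * (i // 4), 25.0 + 45 * (i % 4)) for i in range(10)]
        frame = sum(gaussian_spot(shape, c) for c in centers)
        dets = detect_beads(frame, sigma_px=2.0, threshold_rel=0.3)
        assert len(dets) == 10
        remaining = list(centers)
        for d in dets:
            dists = [np.hypot(d.row - r, d.col - c) for r, c in remaining]
            k = int(np.argmin(dists))
            assert dists[k] < 0.5
            remaining.pop(k)

    def test_global_rescaling_leaves_detections_unchanged(self):
        frame = gaussian_spot((80, 80), (30.0, 44.0)) + gaussian_spot((80, 80), (60.0, 20.0))
        d1 = detect_beads(frame, sigma_px=2.0, threshold_rel=0.4)
        d2 = detect_beads(frame * 7.3, sigma_px=2.0, threshold_rel=0.4)
        assert len(d1) == len(d2) == 2
        np.testing.assert_allclose(
            [(d.row, d.col) for d in d1], [(d.row, d.col) for d in d2], atol=1e-9
        )

    def test_non_2d_input_errors(self):
        with pytest.raises(ValueError, match="2-D"):
            detect_beads(np.zeros((3, 4, 5)))

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.2])
    def test_invalid_threshold_errors(self, threshold):
        with pytest.raises(ValueError, match="threshold_rel"):
            detect_beads(np.zeros((10, 10)), threshold_rel=threshold)


def straight_line_detections(n_frames, start, step, frame0=0):
    return [
        [BeadDetection(frame_index=frame0 + t, row=start[0] + step[0] * t,
                       col=start[1] + step[1] * t, intensity=1.0)]
        for t in range(n_frames)
    ]


class TestLinkTracks:
    def test_single_moving_bead_links_into_one_track(self):
        dets = straight_line_detections(6, (10.0, 10.0), (0.0, 2.0))
        tracks = link_tracks(dets, max_disp_px=5.0, min_len=3)
        assert len(tracks) == 1
        assert tracks[0].n_points == 6

    def test_short_track_discarded(self):
        dets = straight_line_detections(2, (10.0, 10.0), (0.0, 2.0))
        assert link_tracks(dets, max_disp_px=5.0, min_len=3) == []

    def test_two_distant_beads_keep_identity(self):
        a = straight_line_detections(8, (10.0, 10.0), (0.0, 2.0))
        b = straight_line_detections(8, (80.0, 10.0), (0.0, 2.0))
        merged = [fa + fb for fa, fb in zip(a, b)]
        tracks = link_tracks(merged, max_disp_px=5.0, min_len=3)
        assert len(tracks) == 2
        for tr in tracks:
            rows = {round(r) for _, r, _ in tr.points}
            assert len(rows) == 1  # never hops between the two beads

    def test_gate_exceeded_splits_track(self):
        dets = straight_line_detections(8, (10.0, 10.0), (0.0, 6.0))
        tracks = link_tracks(dets, max_disp_px=5.0, min_len=3)
        assert tracks == []  # every jump exceeds the gate -> eight 1-point stubs

    def test_empty_input_gives_empty_output(self):
        assert link_tracks([], max_disp_px=5.0) == []

    def test_every_detection_in_at_most_one_track(self, rng):
        """Conservation: tracked + unassigned = total detections."""
        frames = []
        for t in range(10):
            dets = [
                BeadDetection(t, float(10 + 15 * b + 0.5 * t), float(5 + 2 * t), 1.0)
                for b in range(5)
            ]
            frames.append(dets)
        tracks = link_tracks(frames, max_disp_px=6.0, min_len=3)
        seen = set()
        for tr in tracks:
            for pt in tr.points:
                assert pt not in seen
                seen.add(pt)
        total = sum(len(f) for f in frames)
        assert len(seen) <= total


class TestTrackSpeed:
    def test_two_px_per_frame_at_5fps(self):
        track = BeadTrack(0, [(0, 0.0, 0.0), (1, 0.0, 2.0), (2, 0.0, 4.0)])
        assert track_speed(track, pixel_size_um=1.0, frame_interval_s=0.2) == pytest.approx(10.0)

    def test_stationary_bead_zero_speed(self):
        track = BeadTrack(0, [(0, 5.0, 5.0), (1, 5.0, 5.0), (2, 5.0, 5.0)])
        assert track_speed(track, 1.0, 0.2) == 0.0

    def test_net_mode_below_path_mode_on_jittered_track(self):
        track = BeadTrack(0, [(0, 0.0, 0.0), (1, 1.0, 2.0), (2, -1.0, 4.0), (3, 0.0, 6.0)])
        path = track_speed(track, 1.0, 0.2, mode="path")
        net = track_speed(track, 1.0, 0.2, mode="net")
        assert net <= path
        assert net == pytest.approx(2.0 / 0.2)

    def test_single_point_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            track_speed(BeadTrack(0, [(0, 1.0, 1.0)]), 1.0, 0.2)


class TestEndToEnd:
    def test_five_bead_movie_speeds_within_5_percent(self):
        params = BeadSimParams(
            speeds_um_s=(15.0, 25.0, 35.0, 45.0, 55.0), shape=(288, 704),
            jitter_sigma_px=0.3, seed=21,
        )
        stack, truth = simulate_bead_movie(params)
        config = AnalysisConfig(linking=LinkingConfig(max_disp_px=40.0))
        tables = analyze_bead_movie(stack, config)
        speeds = sorted(tables["speeds"]["speed_um_s"])
        assert len(speeds) == 5
        for est, commanded in zip(speeds, sorted(params.speeds_um_s)):
            assert abs(est - commanded) / commanded <= 0.05

    def test_jittered_speed_bias_matches_monte_carlo_expectation(self):
        """The path-speed estimator's jitter bias is bounded by the
        brute-force expectation E|d + eta| computed from the simulator's own
        parameters (eta per-axis N(0, 2*jitter^2) on each displacement)."""
        speed, jitter, pixel, interval = 35.0, 0.3, 0.4, 0.2
        d_px = speed * interval / pixel
        rng = np.random.default_rng(99)
        eta = rng.normal(0.0, np.sqrt(2) * jitter, size=(200_000, 2))
        expected_step = np.mean(np.hypot(d_px + eta[:, 0], eta[:, 1]))
        expected_speed = expected_step * pixel / interval

        params = BeadSimParams(speeds_um_s=(speed,) * 4, shape=(288, 704),
                               jitter_sigma_px=jitter, seed=5)
        stack, _ = simulate_bead_movie(params)
        tables = analyze_bead_movie(stack, AnalysisConfig(linking=LinkingConfig(max_disp_px=40.0)))
        measured = tables["speeds"]["speed_um_s"].mean()
        # measured speed sits between the commanded value and the MC bias bound,
        # up to detection noise
        assert measured == pytest.approx(expected_speed, rel=0.02)
        assert abs(measured - speed) / speed <= 0.05

    def test_empty_movie_has_empty_tables(self):
        params = BeadSimParams(speeds_um_s=(), seed=1)
        stack, truth = simulate_bead_movie(params)
        tables = analyze_bead_movie(stack)
        assert tables["detections"].empty
        assert tables["speeds"].empty
        assert list(tables["speeds"].columns) == ["track_id", "n_points", "speed_um_s", "region_label"]
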