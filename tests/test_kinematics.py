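"""Carrier preprocessing, detection, tracking and classification tests."""

import numpy as np
import pytest

import golgiscreen as gs
from golgiscreen.kinematics import (
    CarrierDetection,
    CarrierTrack,
    PreprocessParams,
    analyze_timelapse,
    classify_carrier,
    detect_carriers,
    filter_tracks,
    link_tracks,
    percent_cells_with_tubular,
    preprocess,
    track_statistics,
)
from golgiscreen.types import ImageCalibration, ValidationError

CAL = ImageCalibration(pixel_size=0.1, frame_interval=1.0)


class TestPreprocess:
    def test_background_of_ten_vanishes(self):
        assert np.all(preprocess(np.full((16, 16), 10.0)) == 0.0)

    def test_uniform_above_background(self):
        out = preprocess(np.full((16, 16), 25.0))
        assert np.allclose(out, 3 * (25.0 - 10.0))

    def test_below_background_clips_to_zero(self):
        assert np.all(preprocess(np.full((16, 16), 5.0)) == 0.0)

    def test_stack_processed_per_frame(self):
        stack = np.stack([np.full((8, 8), 10.0), np.full((8, 8), 20.0)])
        out = preprocess(stack)
        assert np.all(out[0] == 0.0) and np.allclose(out[1], 30.0)


class TestDetection:
    def _frame(self, length):
        tl = gs.generate_timelapse(
            [gs.CarrierSpec(n_carriers=1, speed=0.0, length=length,
                            start_positions=((25.0, 25.0),))],
            n_frames=2,
            seed=4,
        )
        return preprocess(tl.channels["carrier"])[0], tl.calibration

    def test_tubule_length_recovered(self):
        frame, cal = self._frame(2.5)
        dets = detect_carriers(frame, cal)
        assert len(dets) == 1
        assert dets[0].length_um == pytest.approx(2.5, rel=0.10)

    def test_point_carrier_is_short(self):
        frame, cal = self._frame(0.0)
        dets = detect_carriers(frame, cal)
        assert len(dets) == 1
        assert dets[0].length_um < 2.0

    def test_blank_frame_empty(self):
        assert detect_carriers(np.zeros((64, 64)), CAL) == []


class TestLinking:
    def test_single_carrier_tracked_frame_for_frame(self):
        tl = gs.generate_timelapse(
            [gs.CarrierSpec(n_carriers=1, speed=0.8, start_positions=((20.0, 30.0),))],
            n_frames=12,
            seed=6,
        )
        pre = preprocess(tl.channels["carrier"])
        dets = [detect_carriers(f, tl.calibration, frame_index=i) for i, f in enumerate(pre)]
        tracks = link_tracks(dets, tl.calibration)
        assert len(tracks) == 1
        truth = tl.truth_tracks[0].positions_px(tl.calibration)
        assert len(tracks[0].detections) == len(truth)
        assert np.all(np.hypot(*(tracks[0].positions_px - truth).T) < 1.5)

    def test_two_separated_carriers_no_identity_swap(self):
        tl = gs.generate_timelapse(
            [gs.CarrierSpec(n_carriers=2, speed=0.5,
                            start_positions=((10.0, 10.0), (40.0, 40.0)))],
            n_frames=10,
            seed=7,
        )
        pre = preprocess(tl.channels["carrier"])
        dets = [detect_carriers(f, tl.calibration, frame_index=i) for i, f in enumerate(pre)]
        tracks = link_tracks(dets, tl.calibration)
        assert len(tracks) == 2
        for track, truth in zip(
            sorted(tracks, key=lambda t: t.positions_px[0, 0]),
            sorted(tl.truth_tracks, key=lambda t: t.positions_um[0, 0]),
        ):
            err = np.hypot(*(track.positions_px - truth.positions_px(tl.calibration)).T)
            assert np.all(err < 1.5)

    def test_single_frame_rejected(self):
        with pytest.raises(ValidationError):
            link_tracks([[CarrierDetection(0, (0, 0), 0.0, 1.0)]], CAL)


class TestTrackStatistics:
    def _track(self, positions_um, frames=None):
        frames = frames or list(range(len(positions_um)))
        dets = [
            CarrierDetection(f, (x / CAL.pixel_size, y / CAL.pixel_size), 0.0, 1.0)
            for f, (x, y) in zip(frames, positions_um)
        ]
        return CarrierTrack(detections=dets)

    def test_straight_line(self):
        t = track_statistics(self._track([(0, 0), (1, 0), (2, 0)]), CAL)
        assert t.mean_speed == pytest.approx(1.0)
        assert t.displacement_length == pytest.approx(2.0)

    def test_euclidean_step(self):
        t = track_statistics(self._track([(0, 0), (3, 4)]), CAL)
        assert t.mean_speed == pytest.approx(5.0)

    def test_stationary(self):
        t = track_statistics(self._track([(1, 1), (1, 1), (1, 1)]), CAL)
        assert t.mean_speed == 0.0 and t.displacement_length == 0.0

    def test_displacement_never_exceeds_path(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            pos = rng.uniform(0, 10, size=(6, 2))
            t = track_statistics(self._track(pos), CAL)
            path = t.mean_speed * t.duration
            assert t.displacement_length <= path + 1e-9

    def test_short_track_rejected(self):
        with pytest.raises(ValidationError):
            track_statistics(self._track([(0, 0)]), CAL)


class TestFiltering:
    def _tracks(self, displacements):
        out = []
        for d in displacements:
            t = CarrierTrack()
            t.displacement_length = d
            out.append(t)
        return out

    def test_strictly_greater_than_two(self):
        kept = filter_tracks(self._tracks([2.0, 2.01, 1.0, 5.0]))
        assert [t.displacement_length for t in kept] == [2.01, 5.0]

    def test_empty(self):
        assert filter_tracks([]) == []

    def test_idempotent(self):
        tracks = self._tracks([0.5, 2.5, 3.0])
        once = filter_tracks(tracks)
        assert filter_tracks(once) == once

    def test_frame_mean_criterion_is_stricter_for_returning_tracks(self):
        # out-and-back track: net displacement small, frame-mean moderate
        dets = [
            CarrierDetection(f, (x / CAL.pixel_size, 0.0), 0.0, 1.0)
            for f, x in enumerate([0.0, 3.0, 6.0, 3.0, 0.5])
        ]
        track = track_statistics(CarrierTrack(detections=dets), CAL)
        assert filter_tracks([track]) == []  # net 0.5 µm: dropped
        kept = filter_tracks([track], criterion="frame_mean", calibration=CAL)
        assert kept == [track]  # mean distance from start 3.125 µm: kept


class TestClassification:
    def test_boundary_values(self):
        assert classify_carrier(2.0)[0] == "tubular"
        assert classify_carrier(1.99)[0] == "vesicular"
        assert classify_carrier(3.5) == ("tubular", ">3 µm")

    def test_transition_exactly_at_two_microns(self):
        lengths = np.round(np.arange(0.0, 4.0, 0.01), 10)
        classes = [classify_carrier(l)[0] for l in lengths]
        flips = [l for l, a, b in zip(lengths[1:], classes, classes[1:]) if a != b]
        assert flips == [2.00]

    def test_negative_length_rejected(self):
        with pytest.raises(ValidationError):
            classify_carrier(-0.1)


class TestTubularPrevalence:
    def test_all_cells_tubular(self):
        assert percent_cells_with_tubular({i: [2.5] for i in range(5)}) == 100.0

    def test_no_tubular(self):
        assert percent_cells_with_tubular({i: [1.0, 1.5] for i in range(5)}) == 0.0

    def test_zero_cells_rejected(self):
        with pytest.raises(ValidationError):
            percent_cells_with_tubular({})

    def test_programmed_prevalence_recovered(self):
        """55% of cells given one tubular carrier; estimate within binomial CI."""
        rng = np.random.default_rng(55)
        p, n = 0.55, 100
        cells = [[2.5] if rng.random() < p else [1.2] for _ in range(n)]
        est = percent_cells_with_tubular(cells)
        half_ci = 196.0 * np.sqrt(p * (1 - p) / n)
        assert abs(est - 100 * p) <= half_ci


class TestEndToEnd:
    def test_speed_recovery_clean_videos(self):
        for v in (0.2, 0.5, 1.0):
            tl = gs.generate_timelapse(
                [gs.CarrierSpec(n_carriers=3, speed=v)], n_frames=30, seed=int(v * 10)
            )
            table = analyze_timelapse(tl.channels["carrier"], tl.calibration)
            assert len(table) >= 1
            assert table["mean_speed_um_s"].mean() == pytest.approx(v, rel=0.05)

    def test_single_frame_stack_rejected(self):
        with pytest.raises(ValidationError):
            analyze_timelapse(np.zeros((1, 32, 32)), CAL)

    def test_depletion_arm_speed_ratio(self):
        """An arm with 70% of control speeds reads out at ~70% of control."""
        ratios = []
        for rep in range(3):
            control = gs.generate_timelapse(
                [gs.CarrierSpec(n_carriers=4, speed=0.5)], n_frames=25, seed=100 + rep
            )
            depleted = gs.generate_timelapse(
                [gs.CarrierSpec(n_carriers=4, speed=0.35)], n_frames=25, seed=200 + rep
            )
            s_c = analyze_timelapse(control.channels["carrier"], control.calibration)
            s_d = analyze_timelapse(depleted.channels["carrier"], depleted.calibration)
            ratios.append(s_d["mean_speed_um_s"].mean() / s_c["mean_speed_um_s"].mean())
        assert np.mean(ratios) == pytest.approx(0.70, abs=0.05)
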