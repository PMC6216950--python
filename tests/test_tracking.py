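"""Linking detections into tracks, QC flags, and manual corrections."""

import itertools

import numpy as np
import pytest

import larvaswim as lw
from larvaswim.detection import Detection
from larvaswim.tracking import LinkParams, Track, apply_corrections, flag_tracks, link_tracks


def D(frame, x, y):
    return Detection(frame_index=frame, centroid_px=(float(x), float(y)), area_px=10)


def _track_signature(tracks):
    """Order-free representation: each track as its (frame, x, y) tuple."""
    return sorted(
        tuple((d.frame_index, d.centroid_px) for d in t.detections) for t in tracks
    )


class TestLinkTracks:
    def test_single_detection_per_frame_gives_one_track(self):
        dets = [[D(k, 10 + 2 * k, 20)] for k in range(10)]
        tracks = link_tracks(dets, LinkParams(gate_px=5.0))
        assert len(tracks) == 1
        assert len(tracks[0]) == 10

    def test_empty_input_gives_empty_output(self):
        assert link_tracks([], LinkParams(gate_px=5.0)) == []
        assert link_tracks([[], []], LinkParams(gate_px=5.0)) == []

    def test_detection_beyond_gate_starts_new_track(self):
        dets = [[D(0, 0, 0)], [D(1, 100, 0)]]
        tracks = link_tracks(dets, LinkParams(gate_px=10.0))
        assert len(tracks) == 2

    @pytest.mark.parametrize("method", ["greedy", "optimal"])
    def test_two_separated_larvae_two_tracks(self, method):
        dets = [[D(k, 10 + k, 10), D(k, 200 - k, 180)] for k in range(8)]
        tracks = link_tracks(dets, LinkParams(gate_px=5.0, method=method))
        assert len(tracks) == 2
        assert all(len(t) == 8 for t in tracks)

    def test_greedy_equals_optimal_when_well_separated(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            # two walkers always much further apart than the gate
            a = np.array([50.0, 50.0])
            b = np.array([400.0, 400.0])
            dets = []
            for k in range(12):
                a += rng.uniform(-3, 3, 2)
                b += rng.uniform(-3, 3, 2)
                dets.append([D(k, *a), D(k, *b)])
            g = link_tracks(dets, LinkParams(gate_px=10.0, method="greedy"))
            o = link_tracks(dets, LinkParams(gate_px=10.0, method="optimal"))
            assert _track_signature(g) == _track_signature(o)

    def test_optimal_beats_greedy_on_crossing_geometry(self):
        # frame 0: points at x=0 and x=10; frame 1: at x=4 and x=6.
        # greedy pairs 4<-(nearest overall)… brute-force both assignments:
        p0 = [(0.0, 0.0), (10.0, 0.0)]
        p1 = [(4.0, 0.0), (6.0, 0.0)]

        def total(assign):
            return sum(
                np.hypot(p1[j][0] - p0[i][0], p1[j][1] - p0[i][1])
                for i, j in assign
            )

        brute_best = min(
            total(list(zip(range(2), perm))) for perm in itertools.permutations(range(2))
        )
        dets = [[D(0, *p) for p in p0], [D(1, *p) for p in p1]]

        def linked_total(method):
            tracks = link_tracks(dets, LinkParams(gate_px=50.0, method=method))
            pairs = [
                (p0.index(t.detections[0].centroid_px),
                 p1.index(t.detections[1].centroid_px))
                for t in tracks
                if len(t) == 2
            ]
            return total(pairs)

        assert linked_total("optimal") == pytest.approx(brute_best)
        assert linked_total("optimal") <= linked_total("greedy") + 1e-12

    def test_detections_conserved(self, survey_scene):
        spec, seq, _ = survey_scene
        from larvaswim.detection import DetectionParams, detect_sequence

        dets = detect_sequence(seq.frames[:10], DetectionParams(min_area_px=5,
                                                                merge_distance_px=12.0))
        n_in = sum(len(f) for f in dets)
        tracks = link_tracks(dets, LinkParams(gate_px=40.0))
        n_out = sum(len(t) for t in tracks)
        assert n_in == n_out
        ids = [(d.frame_index, d.centroid_px) for t in tracks for d in t.detections]
        assert len(set(ids)) == len(ids)  # no duplication

    def test_track_count_nonincreasing_in_gate(self):
        rng = np.random.default_rng(4)
        dets = [
            [D(k, x, y) for x, y in rng.uniform(0, 200, (5, 2))] for k in range(6)
        ]
        counts = [
            len(link_tracks(dets, LinkParams(gate_px=g)))
            for g in (1.0, 5.0, 20.0, 100.0, 500.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_gap_closing_with_max_missed_frames(self):
        dets = [[D(0, 10, 10)], [], [D(2, 14, 10)]]
        no_gap = link_tracks(dets, LinkParams(gate_px=10.0, max_missed_frames=0))
        assert len(no_gap) == 2
        gap = link_tracks(dets, LinkParams(gate_px=10.0, max_missed_frames=1))
        assert len(gap) == 1 and len(gap[0]) == 2


class TestFlagTracks:
    def test_fast_step_flagged(self):
        cal = lw.Calibration(cm_per_px=1.0)
        trk = Track(0, [D(0, 0, 0), D(1, 100, 0)])  # 100 cm in 1 s
        rep = flag_tracks([trk], cal, np.array([0.0, 1.0]), speed_cap_cm_s=50.0)
        assert len(rep.fast_steps) == 1
        assert rep.fast_steps[0]["speed_cm_s"] == pytest.approx(100.0)

    def test_clean_synthetic_scene_has_no_speed_or_length_flags(self):
        spec = lw.make_speed_survey_scene(n_larvae=5, n_frames=10, noise_sigma=0.0,
                                          width_px=700, height_px=600, seed=8)
        seq, _ = lw.render_sequence(spec)
        from larvaswim.pipeline import track_sequence

        tracks, _, _ = track_sequence(seq, lw.Calibration(spec.cm_per_px))
        rep = flag_tracks(tracks, lw.Calibration(spec.cm_per_px), seq.timestamps,
                          speed_cap_cm_s=31.0)
        assert rep.fast_steps == [] and rep.short_tracks == []

    def test_detection_count_change_flagged(self):
        tracks = [
            Track(0, [D(0, 0, 0), D(1, 1, 0), D(2, 2, 0)]),
            Track(1, [D(0, 50, 50), D(1, 51, 50)]),  # disappears at frame 2 (merge?)
        ]
        rep = flag_tracks(tracks, lw.Calibration(1.0), np.arange(3.0),
                          speed_cap_cm_s=1e9)
        assert rep.count_change_frames == [2]


class TestApplyCorrections:
    def _two_tracks(self):
        t1 = Track(0, [D(0, 0, 0), D(1, 1, 0)])
        t2 = Track(1, [D(2, 2, 0), D(3, 3, 0)])
        return [t1, t2]

    def test_join_concatenates_and_marks_corrected(self):
        out = apply_corrections(self._two_tracks(),
                                [{"action": "join", "track_ids": [0, 1]}])
        assert len(out) == 1
        assert out[0].frames == [0, 1, 2, 3]
        assert out[0].status == "corrected"

    def test_split_partitions_then_join_restores(self):
        tracks = [Track(0, [D(k, k, 0) for k in range(6)])]
        split = apply_corrections(tracks, [{"action": "split", "track_id": 0,
                                            "at_frame": 3}])
        assert sorted(len(t) for t in split) == [3, 3]
        rejoined = apply_corrections(
            split, [{"action": "join", "track_ids": [t.track_id for t in split]}]
        )
        assert len(rejoined) == 1
        assert [d.centroid_px for d in rejoined[0].detections] == \
            [d.centroid_px for d in tracks[0].detections]

    def test_join_with_frame_collision_rejected(self):
        t1 = Track(0, [D(0, 0, 0), D(1, 1, 0)])
        t2 = Track(1, [D(1, 5, 0), D(2, 6, 0)])
        with pytest.raises(ValueError, match="two detections"):
            apply_corrections([t1, t2], [{"action": "join", "track_ids": [0, 1]}])

    def test_delete_removes_track(self):
        out = apply_corrections(self._two_tracks(), [{"action": "delete", "track_id": 0}])
        assert [t.track_id for t in out] == [1]

    def test_reassign_moves_detection_and_validates(self):
        t1 = Track(0, [D(0, 0, 0), D(1, 1, 0)])
        t2 = Track(1, [D(2, 2, 0)])
        out = apply_corrections([t1, t2], [{"action": "reassign", "frame": 1,
                                            "from_track": 0, "to_track": 1}])
        by_id = {t.track_id: t for t in out}
        assert by_id[0].frames == [0]
        assert by_id[1].frames == [1, 2]
        t3 = Track(2, [D(1, 9, 9)])
        with pytest.raises(ValueError, match="duplicate"):
            apply_corrections([t1, t3], [{"action": "reassign", "frame": 1,
                                          "from_track": 0, "to_track": 2}])

    def test_originals_not_mutated(self):
        tracks = self._two_tracks()
        apply_corrections(tracks, [{"action": "join", "track_ids": [0, 1]}])
        assert len(tracks[0]) == 2 and tracks[0].status == "ok"
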