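"""Scene renderer and chamber-trial simulator: ground truth must be exact."""

import numpy as np
import pandas as pd
import pytest

import larvaswim as lw
from larvaswim.chamber import ChamberProtocol
from larvaswim.synthetic import ONTOGENY_LINES


class TestRenderSequence:
    def test_empty_noiseless_scene_is_uniform_background(self):
        spec = lw.SceneSpec(width_px=64, height_px=48, n_frames=3, fps=4.0,
                            cm_per_px=0.05, background_level=0.8, noise_sigma=0.0)
        seq, truth = lw.render_sequence(spec)
        assert np.all(seq.frames == 0.8)
        assert truth.records.empty

    def test_constant_velocity_truth_advances_expected_pixels(self):
        # 1 cm/s at 0.05 cm/px and 5 fps = 4 px per frame, horizontally
        spec = lw.SceneSpec(
            width_px=300, height_px=100, n_frames=6, fps=5.0, cm_per_px=0.05,
            larvae=(lw.LarvaSpec(start_px=(20.0, 50.0),
                                 trajectory_params={"velocity_cm_s": (1.0, 0.0)}),),
        )
        _, truth = lw.render_sequence(spec)
        t = truth.for_larva(0)
        assert np.allclose(np.diff(t.x_px), 4.0)
        assert np.allclose(np.diff(t.y_px), 0.0)
        assert np.allclose(t.vx_cm_s, 1.0)

    def test_same_seed_renders_bit_identical_frames(self):
        spec = lw.make_speed_survey_scene(n_larvae=3, n_frames=4, width_px=200,
                                          height_px=150, seed=5)
        seq1, t1 = lw.render_sequence(spec)
        seq2, t2 = lw.render_sequence(spec)
        assert np.array_equal(seq1.frames, seq2.frames)
        pd.testing.assert_frame_equal(t1.records, t2.records)

    def test_larvae_render_darker_than_background(self, small_scene):
        spec, seq, truth = small_scene
        r0 = truth.records[truth.records.frame == 0].iloc[0]
        assert seq.frames[0][int(r0.y_px), int(r0.x_px)] < spec.background_level / 2

    @pytest.mark.parametrize("kind,params", [
        ("random_walk", {"step_sd_cm": 0.2}),
        ("vertical_drift", {"drift_cm_s": -1.0, "lateral_sd_cm": 0.05}),
    ])
    def test_truth_velocities_are_finite_differences(self, kind, params):
        spec = lw.SceneSpec(
            width_px=400, height_px=400, n_frames=12, fps=5.0, cm_per_px=0.05,
            larvae=(lw.LarvaSpec(start_px=(200.0, 200.0), trajectory_kind=kind,
                                 trajectory_params=params),),
            seed=11,
        )
        _, truth = lw.render_sequence(spec)
        t = truth.for_larva(0)
        dt = 1 / 5.0
        fd_vx = np.diff(t.x_px) / dt * spec.cm_per_px
        fd_vy = -np.diff(t.y_px) / dt * spec.cm_per_px
        assert np.allclose(fd_vx, t.vx_cm_s[:-1])
        assert np.allclose(fd_vy, t.vy_cm_s[:-1])

    def test_larva_starting_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            lw.SceneSpec(width_px=100, height_px=100,
                         larvae=(lw.LarvaSpec(start_px=(150.0, 50.0)),))

    def test_invalid_scene_parameters_rejected(self):
        with pytest.raises(ValueError):
            lw.SceneSpec(n_frames=1)
        with pytest.raises(ValueError):
            lw.SceneSpec(cm_per_px=0.0)
        with pytest.raises(ValueError):
            lw.LarvaSpec(start_px=(0, 0), opacity=0.0)


class TestChamberTrialSimulation:
    def test_deterministic_failure_at_first_exceeding_increment(self):
        proto = ChamberProtocol(u_i=0.218, t_i=2.0, start_speed=4.782)
        rec = lw.simulate_chamber_trial(5.0, proto)
        assert rec.final_reported_speed == pytest.approx(5.218)
        assert rec.t_final == 0.0
        assert not rec.failed_at_start

    def test_umax_equal_to_start_fails_on_first_increase(self):
        proto = ChamberProtocol(u_i=0.218, t_i=2.0, start_speed=3.0)
        rec = lw.simulate_chamber_trial(3.0, proto)
        assert rec.final_reported_speed == pytest.approx(3.0 + 0.218)

    def test_umax_below_start_is_flagged(self):
        proto = ChamberProtocol(start_speed=5.0)
        rec = lw.simulate_chamber_trial(2.0, proto)
        assert rec.failed_at_start

    def test_estimate_within_one_increment_of_truth(self):
        proto = ChamberProtocol(u_i=0.218, t_i=2.0, start_speed=5.0)
        for k in range(100):
            rec = lw.simulate_chamber_trial(10.0, proto, seed=k)
            est = lw.compute_umax(rec, proto).u_max
            assert 0 <= 10.0 - est <= 0.218 + 1e-12

    def test_stochastic_mode_reproducible_and_plausible(self):
        proto = ChamberProtocol(start_speed=5.0)
        a = lw.simulate_chamber_trial(10.0, proto, seed=3, mode="stochastic")
        b = lw.simulate_chamber_trial(10.0, proto, seed=3, mode="stochastic")
        assert a == b
        assert 0 <= a.t_final < proto.t_i


class TestChamberDataset:
    def test_campaign_table_shape_and_ranges(self):
        df = lw.simulate_chamber_dataset(seed=2)
        assert set(df.columns) >= {"fish_id", "species", "dph", "stage", "tl_cm",
                                   "final_reported_speed", "t_final"}
        assert set(df.species.unique()) == {"bighead", "grass", "silver"}
        assert df.stage.between(31, 48).all()
        assert (df.tl_cm > 0).all()
        # 10-20 fish per species-day
        per_day = df.groupby(["species", "dph"]).size()
        assert per_day.between(10, 20).all()

    def test_campaign_deterministic_given_seed(self):
        a = lw.simulate_chamber_dataset(seed=9)
        b = lw.simulate_chamber_dataset(seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_silver_carp_first_day_cohort_recovers_generator_mean(self):
        # a 4-DPH silver-carp-like cohort: true U_max ~ N(2.56, 0.67)
        rng = np.random.default_rng(12)
        proto = ChamberProtocol(u_i=0.218, t_i=2.0, start_speed=1.0)
        true = rng.normal(2.56, 0.67, size=50).clip(1.2)
        ests = [
            lw.compute_umax(lw.simulate_chamber_trial(u, proto), proto).u_max
            for u in true
        ]
        assert np.mean(ests) == pytest.approx(2.56, abs=0.3)

    def test_derived_length_and_stage_trajectories_are_consistent(self):
        # inverting the species lines must reproduce U_max at any age
        for lines in ONTOGENY_LINES.values():
            u = lines["dph"](10.0)
            assert lines["length_mm"](lines["length_mm"].invert(u)) == pytest.approx(u)
            assert lines["stage"](lines["stage"].invert(u)) == pytest.approx(u)
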