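"""Virtual instrument: drag and creep trajectories, image rendering,
population sampling and synthetic fiber volumes."""

import numpy as np
import pytest

import magrheo as m
from magrheo.simulate import simulate_calibration_table


class TestDragTrajectory:
    def test_no_force_no_drift_is_stationary(self, drag_truth, quiet_cfg):
        traj = m.simulate_drag_trajectory(drag_truth, 4.85, 2.25, [],
                                          100.0, quiet_cfg, duration_s=1.0)
        np.testing.assert_allclose(traj.x_um, 100.0)
        assert not traj.truncated

    def test_initial_speed_matches_stokes(self, example_cal):
        # F(1 A, 50 µm) = 29.9 nN -> v = F/(6 pi eta R) = 242 µm/s
        cfg = m.SimulationConfig(frame_rate_hz=2000.0)
        traj = m.simulate_drag_trajectory(example_cal, 2.91, 2.25,
                                          [(0.0, 0.01, 1.0)], 50.0, cfg,
                                          duration_s=0.002)
        v0 = (traj.x_um[0] - traj.x_um[1]) / (traj.time_s[1] - traj.time_s[0])
        expected = 29.909 * 1e3 / (6 * np.pi * 2.91 * 2.25)
        assert v0 == pytest.approx(expected, rel=0.01)

    def test_off_phase_slope_equals_drift(self, drag_truth):
        cfg = m.SimulationConfig(drift_velocity_um_s=0.1)
        # 2 s on / 2 s off calibration-style pulse
        traj = m.simulate_drag_trajectory(drag_truth, 4.85, 2.25,
                                          [(2.0, 4.0, 0.3)], 120.0, cfg,
                                          duration_s=6.0)
        off = traj.time_s < 2.0
        slope = np.polyfit(traj.time_s[off], traj.x_um[off], 1)[0]
        assert slope == pytest.approx(0.1, rel=1e-6)

    def test_monotone_approach_during_pulse(self, drag_truth, quiet_cfg):
        traj = m.simulate_drag_trajectory(drag_truth, 4.85, 2.25,
                                          [(0.0, 1.0, 0.8)], 120.0, quiet_cfg,
                                          duration_s=1.0)
        assert np.all(np.diff(traj.x_um) < 0)

    def test_velocity_consistent_with_force_everywhere(self, drag_truth):
        # drag-consistency invariant: central-difference velocity equals
        # F(I, d)/(6 pi eta R) at the sampled distances
        cfg = m.SimulationConfig(frame_rate_hz=200.0)
        traj = m.simulate_drag_trajectory(drag_truth, 4.85, 2.25,
                                          [(0.0, 1.0, 0.9)], 120.0, cfg,
                                          duration_s=1.0)
        t, x = traj.time_s, traj.x_um
        v = -(x[2:] - x[:-2]) / (t[2:] - t[:-2])
        d_mid = x[1:-1]
        expected = np.array([m.force_at(drag_truth, 0.9, d,
                                        warn_extrapolation=False)
                             for d in d_mid]) * 1e3 / (6 * np.pi * 4.85 * 2.25)
        np.testing.assert_allclose(v, expected, rtol=0.01)

    def test_truncation_when_bead_reaches_needle(self, drag_truth, quiet_cfg):
        traj = m.simulate_drag_trajectory(drag_truth, 0.5, 2.25,
                                          [(0.0, 30.0, 1.0)], 60.0, quiet_cfg,
                                          duration_s=30.0)
        assert traj.truncated
        assert traj.x_um[-1] > 0

    def test_start_outside_validity_rejected(self, drag_truth, quiet_cfg):
        with pytest.raises(ValueError):
            m.simulate_drag_trajectory(drag_truth, 4.85, 2.25, [], 500.0,
                                       quiet_cfg)


class TestCreepDisplacement:
    def test_zero_force_gives_zero_displacement(self, cell_material, quiet_cfg):
        prot = m.ForceProtocol(())
        traj = m.simulate_creep_displacement(cell_material, prot, 2.25,
                                             quiet_cfg, duration_s=2.0)
        np.testing.assert_allclose(traj.displacement_um(), 0.0, atol=1e-15)

    def test_elastic_plateau_100nm(self, quiet_cfg):
        # J = 7.069e-4 1/Pa, F = 1 nN, r = 2.25 µm -> d = J F/(pi r) = 100 nm
        mat = m.MaterialModel("power_law", J0=7.069e-4, beta=0.0)
        prot = m.ForceProtocol.single_pulse(1.0, 2.0, t_start=0.5)
        traj = m.simulate_creep_displacement(mat, prot, 2.25, quiet_cfg)
        disp = traj.displacement_um()
        on = (traj.time_s > 0.5) & (traj.time_s < 2.5)
        np.testing.assert_allclose(disp[on], 0.10001, rtol=1e-4)

    def test_superposition_closed_form_after_off(self, quiet_cfg):
        # beta = 0.5, on at 0 / off at 2: d(4)/scale = 4^0.5 - 2^0.5
        mat = m.MaterialModel("power_law", J0=1.0, beta=0.5)
        prot = m.ForceProtocol.single_pulse(1.0, 2.0)
        traj = m.simulate_creep_displacement(mat, prot, 2.25, quiet_cfg,
                                             duration_s=4.0)
        scale = 1e3 * 1.0 / (np.pi * 2.25)
        d4 = traj.displacement_um()[-1]
        assert d4 / scale == pytest.approx(np.sqrt(4) - np.sqrt(2), rel=1e-12)

    def test_linearity_in_force(self, cell_material, quiet_cfg):
        p1 = m.ForceProtocol.pulse_train(1.0, 2.0, 2.0, 3)
        p2 = m.ForceProtocol.pulse_train(2.0, 2.0, 2.0, 3)
        d1 = m.simulate_creep_displacement(cell_material, p1, 2.25, quiet_cfg)
        d2 = m.simulate_creep_displacement(cell_material, p2, 2.25, quiet_cfg)
        np.testing.assert_allclose(d2.displacement_um(),
                                   2 * d1.displacement_um(), atol=1e-12)

    def test_reproducible_under_fixed_seed(self, cell_material):
        cfg = m.SimulationConfig(noise_sd_position_um=0.01, seed=123)
        prot = m.ForceProtocol.single_pulse(1.0, 2.0)
        a = m.simulate_creep_displacement(cell_material, prot, 2.25, cfg)
        b = m.simulate_creep_displacement(cell_material, prot, 2.25, cfg)
        np.testing.assert_array_equal(a.x_um, b.x_um)

    def test_negative_force_protocol_rejected(self):
        with pytest.raises(ValueError):
            m.ForceProtocol(((0.0, -1.0),))


class TestRenderImageSequence:
    def test_empty_trajectory_renders_needle_only(self, quiet_cfg):
        traj = m.BeadTrajectory(np.empty(0), np.empty(0), np.empty(0), 2.25)
        needle = m.NeedleGeometry(tip_position_um=(2.0, 7.2))
        stack = m.render_image_sequence(traj, needle, quiet_cfg, shape=(96, 96))
        assert len(stack) == 1
        assert (stack.frames[0] < 3000).any()  # needle pixels are dark

    def test_bead_disk_diameter_30px(self):
        # 4.5 µm bead at 0.15 µm/px -> 30 px disk
        cfg = m.SimulationConfig(pixel_size_um=0.15)
        traj = m.BeadTrajectory([0.0], [9.6], [7.2], 2.25)
        needle = m.NeedleGeometry(tip_position_um=(-40.0, 7.2))
        stack = m.render_image_sequence(traj, needle, cfg, shape=(96, 128))
        dark = stack.frames[0] < 2000
        widths = dark.sum(axis=1)
        assert widths.max() == pytest.approx(30, abs=1)

    def test_wedge_half_angle_measurable(self):
        # the conical flanks only start ~7 µm behind the rounded tip
        # (tangency of the 10 µm curvature disk), so measure the width
        # growth on the straight part of the silhouette, well behind it
        cfg = m.SimulationConfig(pixel_size_um=0.5)
        needle = m.NeedleGeometry(tip_position_um=(100.0, 32.0),
                                  opening_angle_deg=35.0,
                                  orientation=(-1.0, 0.0))
        traj = m.BeadTrajectory(np.empty(0), np.empty(0), np.empty(0), 2.25)
        stack = m.render_image_sequence(traj, needle, cfg, shape=(128, 224))
        mask = stack.frames[0] < 2000
        cols = np.arange(224)
        x_um = cols * 0.5
        widths = mask.sum(axis=0).astype(float) * 0.5
        sel = (x_um >= 50.0) & (x_um <= 85.0)
        slope = np.polyfit(x_um[sel], widths[sel], 1)[0]
        half_angle = np.degrees(np.arctan(abs(slope) / 2.0))
        assert half_angle == pytest.approx(17.5, abs=0.5)

    def test_position_outside_frame_rejected(self, quiet_cfg):
        traj = m.BeadTrajectory([0.0], [1e4], [0.0], 2.25)
        needle = m.NeedleGeometry()
        with pytest.raises(ValueError):
            m.render_image_sequence(traj, needle, quiet_cfg)

    def test_one_frame_per_sample(self, quiet_cfg):
        t = np.arange(5) / 40
        traj = m.BeadTrajectory(t, np.full(5, 9.0), np.full(5, 7.0), 2.25)
        needle = m.NeedleGeometry(tip_position_um=(1.0, 7.0))
        stack = m.render_image_sequence(traj, needle, quiet_cfg)
        assert len(stack) == 5
        np.testing.assert_array_equal(stack.timestamps, t)


class TestNeedleGeometry:
    def test_surface_distance_on_axis(self):
        needle = m.NeedleGeometry(tip_position_um=(0.0, 0.0),
                                  orientation=(-1.0, 0.0))
        assert needle.surface_distance((30.0, 0.0)) == pytest.approx(30.0)
        assert needle.surface_distance((-5.0, 0.0)) == 0.0  # inside

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            m.NeedleGeometry(opening_angle_deg=0.0)
        with pytest.raises(ValueError):
            m.NeedleGeometry(tip_curvature_radius_um=-1.0)


class TestSamplePopulation:
    def test_zero_spread_collapses(self):
        s = m.sample_population(np.log(300), 0.0, 0.4, 0.0, n=5, seed=0)
        np.testing.assert_allclose(s.stiffness_pa, 300.0)
        np.testing.assert_allclose(s.fluidity, 0.4)

    def test_geometric_mean_monte_carlo(self):
        s = m.sample_population(np.log(300), 0.5, 0.46, 0.1, n=10000, seed=1)
        gm = np.exp(np.mean(np.log(s.stiffness_pa)))
        assert gm == pytest.approx(300.0, rel=0.02)

    def test_determinism(self):
        a = m.sample_population(n=3, seed=9)
        b = m.sample_population(n=3, seed=9)
        np.testing.assert_array_equal(a.stiffness_pa, b.stiffness_pa)
        np.testing.assert_array_equal(a.fluidity, b.fluidity)

    def test_beta_clipped_and_reported(self):
        s = m.sample_population(np.log(300), 0.5, 0.5, 5.0, n=2000, seed=2)
        assert np.all((s.fluidity >= 0) & (s.fluidity <= 1))
        assert s.n_clipped_low > 0 and s.n_clipped_high > 0


class TestSyntheticVolumes:
    def test_zero_fibers_all_fluid(self):
        _, gt = m.synth_collagen_volume((32, 32, 32), fiber_count=0, seed=0)
        assert not gt.voxels.any()

    def test_sphere_fixture_by_construction(self):
        vol = m.synth_cavity_volume((64, 64, 64), cavities=((None, 8.0),))
        fluid = ~vol.voxels
        assert fluid.sum() == pytest.approx(4 / 3 * np.pi * 8 ** 3, rel=0.1)

    def test_determinism(self):
        a, am = m.synth_collagen_volume((32, 32, 32), fiber_count=20, seed=4)
        b, bm = m.synth_collagen_volume((32, 32, 32), fiber_count=20, seed=4)
        np.testing.assert_array_equal(a.voxels, b.voxels)
        np.testing.assert_array_equal(am.voxels, bm.voxels)

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValueError):
            m.synth_collagen_volume((16, 64, 64))

    def test_fiber_radius_too_large_rejected(self):
        with pytest.raises(ValueError):
            m.synth_collagen_volume((32, 32, 32), fiber_radius_vox=10.0)


class TestCalibrationTable:
    def test_table_has_expected_grid(self, drag_truth, quiet_cfg):
        tab = simulate_calibration_table(drag_truth, [0.4, 0.8], [90, 110],
                                         4.85, 2.25, quiet_cfg)
        assert len(tab) == 4
        assert set(tab.columns) == {"current_A", "distance_um", "velocity_um_s"}
        assert (tab.velocity_um_s > 0).all()
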