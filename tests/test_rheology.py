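"""Creep rheology: compliance scaling, model fits, superposition, protocol
analysis and recovery."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import magrheo as m
from magrheo.rheology import (StaircaseResult, compliance_to_displacement,
                              fit_pulse_train, fit_recovery, fit_staircase)


class TestDisplacementToCompliance:
    def test_zero_displacement_zero_compliance(self):
        c = m.displacement_to_compliance([0.1, 0.2], [0.0, 0.0], 1.0, 2.25)
        np.testing.assert_array_equal(c.J, 0.0)

    def test_hand_value_100nm(self):
        c = m.displacement_to_compliance([1.0], [0.1], 1.0, 2.25)
        assert c.J[0] == pytest.approx(7.069e-4, rel=1e-3)
        assert 1.0 / c.J[0] == pytest.approx(1414.0, rel=1e-3)

    def test_40nm_detection_limit_is_3p5kpa(self):
        # the smallest detectable displacement at 1 nN bounds the stiffest
        # measurable material: ~3.5 kPa
        c = m.displacement_to_compliance([1.0], [0.040], 1.0, 2.25)
        assert 1.0 / c.J[0] == pytest.approx(3500.0, rel=0.02)

    def test_zero_force_rejected(self):
        with pytest.raises(ValueError):
            m.displacement_to_compliance([1.0], [0.1], 0.0, 2.25)

    @given(st.floats(0.2, 5.0), st.floats(0.5, 5.0))
    def test_linear_in_displacement_inverse_in_force(self, scale_d, scale_f):
        t = np.linspace(0.1, 2, 10)
        d = 0.05 * t ** 0.4
        base = m.displacement_to_compliance(t, d, 1.0, 2.25)
        scaled = m.displacement_to_compliance(t, scale_d * d, scale_f, 2.25)
        np.testing.assert_allclose(scaled.J, base.J * scale_d / scale_f,
                                   rtol=1e-12)

    def test_round_trip_with_inverse(self):
        J = np.array([1e-3, 2e-3])
        d = compliance_to_displacement(J, 1.0, 2.25)
        back = m.displacement_to_compliance([1.0, 2.0], d, 1.0, 2.25)
        np.testing.assert_allclose(back.J, J, rtol=1e-12)


class TestPowerLawFit:
    def test_noiseless_recovery(self):
        t = np.arange(1, 81) / 40
        curve = m.CreepCurve(t, 1e-3 * t ** 0.4, stress_pa=1.0)
        fit = m.fit_power_law(curve)
        assert fit.J0 == pytest.approx(1e-3, rel=1e-6)
        assert fit.beta == pytest.approx(0.4, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_curve_is_elastic(self):
        t = np.arange(1, 41) / 40
        fit = m.fit_power_law(m.CreepCurve(t, np.full_like(t, 2e-3), 1.0))
        assert fit.J0 == pytest.approx(2e-3, rel=1e-9)
        assert fit.beta == pytest.approx(0.0, abs=1e-9)

    def test_noisy_beta_bias_small(self):
        rng = np.random.default_rng(17)
        t = np.arange(1, 81) / 40
        betas = []
        for _ in range(200):
            J = 1e-3 * t ** 0.4 * (1 + rng.normal(0, 0.05, t.size))
            betas.append(m.fit_power_law(m.CreepCurve(t, J, 1.0)).beta)
        assert abs(np.mean(betas) - 0.4) < 0.01

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            m.fit_power_law(m.CreepCurve(np.array([0.1, 0.2]),
                                         np.array([1e-3, 1e-3]), 1.0))


class TestKelvinVoigtFit:
    def test_noiseless_recovery(self):
        t = np.arange(1, 81) / 40
        J = 2e-3 * (1 - np.exp(-t / 0.5))
        fit = m.fit_kelvin_voigt(m.CreepCurve(t, J, 1.0))
        assert fit.J0 == pytest.approx(2e-3, rel=1e-6)
        assert fit.tau == pytest.approx(0.5, rel=1e-6)

    def test_plateau_only_flags_tau(self):
        t = np.linspace(10.0, 12.0, 20)  # t >> tau: only the plateau visible
        J = 2e-3 * (1 - np.exp(-t / 0.1))
        fit = m.fit_kelvin_voigt(m.CreepCurve(t, J, 1.0))
        assert fit.J0 == pytest.approx(2e-3, rel=1e-3)
        assert fit.flags.get("tau_poorly_constrained")

    def test_power_law_data_fits_power_law_better(self):
        t = np.arange(1, 81) / 40
        J = 1e-3 * t ** 0.4
        curve = m.CreepCurve(t, J, 1.0)
        assert m.fit_power_law(curve).r_squared > m.fit_kelvin_voigt(curve).r_squared

    def test_model_ordering_under_noise(self):
        # power-law creep prefers the power-law model in >=95% of replicates
        rng = np.random.default_rng(23)
        t = np.arange(1, 81) / 40
        wins = 0
        n = 100
        for _ in range(n):
            J = 1e-3 * t ** 0.4 * (1 + rng.normal(0, 0.05, t.size))
            curve = m.CreepCurve(t, J, 1.0)
            if m.fit_power_law(curve).r_squared > m.fit_kelvin_voigt(curve).r_squared:
                wins += 1
        assert wins >= 0.95 * n


class TestSuperpose:
    def test_single_event_reduction(self, cell_material):
        prot = m.ForceProtocol(((0.0, 1.0),))
        t = np.linspace(0, 2, 81)
        d = m.superpose(cell_material, prot, 2.25, t)
        expected = compliance_to_displacement(cell_material.compliance(t), 1.0, 2.25)
        np.testing.assert_allclose(d, expected, rtol=1e-12)

    def test_closed_form_off_phase(self):
        mat = m.MaterialModel("power_law", J0=1.0, beta=0.5)
        prot = m.ForceProtocol.single_pulse(1.0, 2.0)
        d4 = m.superpose(mat, prot, 2.25, np.array([4.0]))[0]
        scale = 1e3 / (np.pi * 2.25)
        assert d4 / scale == pytest.approx(np.sqrt(4) - np.sqrt(2), rel=1e-12)

    def test_kelvin_voigt_full_recovery(self):
        mat = m.MaterialModel("kelvin_voigt", J0=2e-3, tau=0.3)
        prot = m.ForceProtocol.single_pulse(1.0, 2.0)
        d = m.superpose(mat, prot, 2.25, np.array([30.0]))[0]
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_convolution(self, cell_material):
        # independent oracle: convolve dF/dt (deltas on a fine grid) with J
        prot = m.ForceProtocol.pulse_train(1.0, 2.0, 2.0, 3)
        dt = 5e-4
        grid = np.arange(0.0, prot.t_end + 2.0 + dt, dt)
        force = prot.force_at(grid)
        dF = np.diff(force, prepend=0.0)
        J = cell_material.compliance(grid)
        conv = np.convolve(dF, J)[:grid.size]
        d_ref = conv * 1e3 / (np.pi * 2.25)
        sample_t = np.arange(0, (prot.t_end + 2.0) * 40 + 1) / 40
        d = m.superpose(cell_material, prot, 2.25, sample_t)
        ref = np.interp(sample_t, grid, d_ref)
        peak = np.max(np.abs(d))
        assert np.max(np.abs(d - ref)) / peak < 1e-3


class TestPulseTrain:
    def _train(self, cfg=None, mats=None, cell=None):
        cell = cell or m.MaterialModel("power_law", J0=1 / 300, beta=0.45)
        prot = m.ForceProtocol.pulse_train(1.0, 2.0, 2.0, 10, t_start=1.0)
        cfg = cfg or m.SimulationConfig()
        traj = m.simulate_creep_displacement(cell, prot, 2.25, cfg,
                                             materials_per_event=mats)
        return prot, traj

    def test_time_invariant_material_constant_stiffness(self):
        prot, traj = self._train()
        fits = fit_pulse_train(traj, prot)
        stiff = np.array([f.stiffness_pa for f in fits])
        assert len(fits) == 10
        np.testing.assert_allclose(stiff, 300.0, rtol=1e-3)

    def test_programmed_stiffening_is_monotone(self):
        prot = m.ForceProtocol.pulse_train(1.0, 2.0, 2.0, 10, t_start=1.0)
        mats, k = [], -1
        for _, df in prot.events:
            if df > 0:
                k += 1
            mats.append(m.MaterialModel("power_law", J0=(1 / 300) / 1.05 ** k,
                                        beta=0.45))
        traj = m.simulate_creep_displacement(
            m.MaterialModel("power_law", J0=1 / 300, beta=0.45), prot, 2.25,
            m.SimulationConfig(), materials_per_event=mats)
        fits = fit_pulse_train(traj, prot)
        stiff = [f.stiffness_pa for f in fits]
        assert all(b > a for a, b in zip(stiff, stiff[1:]))
        assert stiff[0] == pytest.approx(300.0, rel=1e-2)

    def test_empty_protocol_empty_result(self, cell_material, quiet_cfg):
        prot = m.ForceProtocol(())
        traj = m.simulate_creep_displacement(cell_material, prot, 2.25,
                                             quiet_cfg, duration_s=2.0)
        assert fit_pulse_train(traj, prot) == []


class TestStaircase:
    def test_linear_material_fold_change_one(self, cell_material, quiet_cfg):
        prot = m.ForceProtocol.staircase(1, 1, 5, 2.0, t_start=1.0)
        traj = m.simulate_creep_displacement(cell_material, prot, 2.25, quiet_cfg)
        res = fit_staircase(traj, prot)
        assert isinstance(res, StaircaseResult)
        assert res.stiffness_fold_change == pytest.approx(1.0, abs=1e-3)
        assert len(res.fits) == 5

    def test_stress_stiffening_sqrt5_recovered(self, quiet_cfg):
        # J0^-1(F) = J0^-1(1 nN) * sqrt(F): fold change sqrt(5) over 1->5 nN
        prot = m.ForceProtocol.staircase(1, 1, 5, 2.0, t_start=1.0)
        mats, level = [], 0.0
        for _, df in prot.events:
            if df > 0:
                level += df
            mats.append(m.MaterialModel("power_law",
                                        J0=1 / (300 * np.sqrt(level)),
                                        beta=0.45))
        traj = m.simulate_creep_displacement(
            m.MaterialModel("power_law", J0=1 / 300, beta=0.45), prot, 2.25,
            quiet_cfg, materials_per_event=mats)
        res = fit_staircase(traj, prot)
        assert res.stiffness_fold_change == pytest.approx(np.sqrt(5), rel=0.01)

    def test_fold_change_arithmetic(self):
        ratio, _ = m.fold_change([100.0, 130.0, 231.0])
        assert ratio == pytest.approx(2.31)

    def test_short_steps_rejected(self, cell_material):
        prot = m.ForceProtocol.staircase(1, 1, 3, 0.05, t_start=0.5)
        cfg = m.SimulationConfig(frame_rate_hz=40.0)
        traj = m.simulate_creep_displacement(cell_material, prot, 2.25, cfg)
        with pytest.raises(ValueError):
            fit_staircase(traj, prot)


class TestRecovery:
    def _single_pulse_traj(self, creep_mat, recovery_mat=None, cfg=None):
        prot = m.ForceProtocol.single_pulse(1.0, 2.0, t_start=1.0)
        mats = None
        if recovery_mat is not None:
            mats = [creep_mat, recovery_mat]
        cfg = cfg or m.SimulationConfig()
        traj = m.simulate_creep_displacement(creep_mat, prot, 2.25, cfg,
                                             duration_s=5.0,
                                             materials_per_event=mats)
        return prot, traj

    def _creep_fit(self, traj, t_on=1.0, t_off=3.0):
        mask = (traj.time_s > t_on) & (traj.time_s <= t_off)
        disp = traj.displacement_um()
        curve = m.displacement_to_compliance(traj.time_s[mask] - t_on,
                                             disp[mask], 1.0, 2.25)
        return m.fit_power_law(curve)

    def test_symmetric_recovery_matches_creep(self, cell_material):
        prot, traj = self._single_pulse_traj(cell_material)
        cf = self._creep_fit(traj)
        rf = fit_recovery(traj, cf, 3.0, 1.0, 2.25, t_on_s=1.0)
        assert rf.recovery_J0 == pytest.approx(cf.J0, rel=1e-3)
        assert rf.recovery_beta == pytest.approx(cf.beta, abs=1e-3)
        assert "no_recovery" not in rf.flags

    def test_purely_elastic_instant_full_recovery(self):
        mat = m.MaterialModel("power_law", J0=1 / 500, beta=0.0)
        prot, traj = self._single_pulse_traj(mat)
        cf = self._creep_fit(traj)
        rf = fit_recovery(traj, cf, 3.0, 1.0, 2.25, t_on_s=1.0)
        assert rf.recovery_stiffness_pa == pytest.approx(cf.stiffness_pa, rel=1e-3)

    def test_halved_recovery_compliance_doubles_stiffness(self, cell_material):
        rec = m.MaterialModel("power_law", J0=cell_material.J0 / 2, beta=0.45)
        prot, traj = self._single_pulse_traj(cell_material, recovery_mat=rec)
        cf = self._creep_fit(traj)
        rf = fit_recovery(traj, cf, 3.0, 1.0, 2.25, t_on_s=1.0)
        assert rf.recovery_stiffness_pa == pytest.approx(2 * cf.stiffness_pa,
                                                         rel=1e-2)

    def test_no_recovery_flagged(self, cell_material, quiet_cfg):
        # force never switched off: displacement keeps increasing
        prot = m.ForceProtocol(((1.0, 1.0),))
        traj = m.simulate_creep_displacement(cell_material, prot, 2.25,
                                             quiet_cfg, duration_s=6.0)
        cf = self._creep_fit(traj)
        rf = fit_recovery(traj, cf, 3.0, 1.0, 2.25, t_on_s=1.0)
        assert rf.flags.get("no_recovery")


class TestParameterRecoveryUnderNoise:
    def test_powerlaw_recovery_5pct_noise(self):
        # 200 replicates at 5% displacement noise, 40 Hz, 2 s
        rng = np.random.default_rng(31)
        t = np.arange(1, 81) / 40
        true_J0, true_beta = 1 / 300, 0.45
        d_clean = compliance_to_displacement(true_J0 * t ** true_beta, 1.0, 2.25)
        sd = 0.05 * d_clean[-1]
        J0s, betas = [], []
        for _ in range(200):
            d = d_clean + rng.normal(0, sd, t.size)
            fit = m.fit_power_law(m.displacement_to_compliance(t, d, 1.0, 2.25))
            J0s.append(fit.J0)
            betas.append(fit.beta)
        assert 1 / np.mean(J0s) == pytest.approx(300.0, rel=0.05)
        assert abs(np.mean(betas) - true_beta) < 0.02
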