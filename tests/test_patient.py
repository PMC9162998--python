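"""Virtual heart-failure plant: PK/PD, volume handling and the closed loop."""

import math

import numpy as np
import pandas as pd
import pytest

import hemoloop as hl
from hemoloop.patient import _observe


class TestMakePatient:
    def test_drug_free_equilibrium_reproduces_baseline(self, patient):
        sol = hl.solve_equilibrium(patient.baseline, patient.constants)
        base = patient.baseline_state
        for f in ("AP", "CO", "P_LA", "P_RA"):
            assert getattr(sol, f) == pytest.approx(getattr(base, f), rel=1e-8)

    def test_default_baseline_is_hf_canine(self, patient):
        s = patient.baseline_state
        assert s.AP == 87.0
        assert s.P_LA == 17.0
        assert s.CO == 118.0
        assert s.HR == 129.0

    def test_same_seed_same_patient(self):
        cfg = hl.PatientConfig(ensemble_cv=0.1)
        p1 = hl.make_hf_patient(cfg, seed=42)
        p2 = hl.make_hf_patient(cfg, seed=42)
        assert p1.baseline == p2.baseline

    def test_ensemble_seeds_differ(self):
        cfg = hl.PatientConfig(ensemble_cv=0.1)
        p1 = hl.make_hf_patient(cfg, seed=1)
        p2 = hl.make_hf_patient(cfg, seed=2)
        assert p1.baseline_state.AP != p2.baseline_state.AP

    def test_infeasible_baseline_raises(self):
        with pytest.raises(hl.DomainError):
            hl.make_hf_patient(hl.PatientConfig(P_LA=1.0))  # below curve offset


class TestPlantStep:
    def test_drug_free_plant_is_fixed_point(self, patient):
        s = hl.initial_plant_state(patient)
        for i in range(20):
            s, obs = hl.plant_step(patient, s, 0.0, 0.0, 0.0, dt=1 / 6)
            assert obs.AP == pytest.approx(patient.baseline_state.AP, rel=1e-9)
            assert obs.P_LA == pytest.approx(patient.baseline_state.P_LA, rel=1e-9)
        assert s.C == 0.0
        assert s.V_current == patient.baseline.V

    def test_pk_steady_state_matches_closed_form(self, patient):
        rate, dt = 26.0, 1 / 6
        k_e, vd = patient.pk.k_e, patient.pk.Vd
        s = hl.initial_plant_state(patient)
        t, half_life = 0.0, math.log(2) / k_e
        while t < 7 * half_life:
            s, _ = hl.plant_step(patient, s, rate, 0.0, 0.0, dt)
            t += dt
        assert s.C == pytest.approx(rate / (k_e * vd), rel=0.01)

    def test_pk_mass_balance_without_elimination(self):
        cfg = hl.PatientConfig(pk=hl.PKParams(k_e=0.0, Vd=300.0))
        p = hl.make_hf_patient(cfg)
        s = hl.initial_plant_state(p)
        rate, dt, n = 10.0, 1 / 6, 60
        for _ in range(n):
            s, _ = hl.plant_step(p, s, rate, 0.0, 0.0, dt)
        assert s.C * p.pk.Vd == pytest.approx(rate * dt * n, rel=1e-12)

    def test_dextran_retention_fraction(self, patient):
        s0 = hl.initial_plant_state(patient)
        s1, _ = hl.plant_step(patient, s0, 0.0, 1.2, 0.0, dt=0.5)
        gained = s1.V_current - s0.V_current
        assert gained == pytest.approx(patient.dextran_fraction * 1.2 * 0.5)

    def test_furosemide_bolus_drains_first_order(self, patient):
        s0 = hl.initial_plant_state(patient)
        dose, dt = 5.0, 1.0
        s1, _ = hl.plant_step(patient, s0, 0.0, 0.0, dose, dt)
        queued = patient.furo.gain * dose
        expressed = queued * (1 - math.exp(-patient.furo.onset_rate * dt))
        assert s0.V_current - s1.V_current == pytest.approx(expressed)
        assert s1.pending_diuresis == pytest.approx(queued - expressed)

    def test_steady_state_dose_response_monotone(self, patient):
        rows = []
        for rate in (0.0, 10.0, 20.0, 40.0):
            s = hl.initial_plant_state(patient)
            for _ in range(360):  # 60 min at constant infusion
                s, obs = hl.plant_step(patient, s, rate, 0.0, 0.0, dt=1 / 6)
            rows.append((s.S_L_current, s.HR_current, obs.CO, obs.AP))
        arr = np.array(rows)
        assert np.all(np.diff(arr, axis=0) < 0)  # S_L, HR, CO, AP all fall

    def test_volume_depletion_raises_simulation_fault(self, patient):
        s = hl.initial_plant_state(patient)
        cfg = hl.PatientConfig(furo=hl.FurosemideParams(gain=100.0, onset_rate=50.0))
        p = hl.make_hf_patient(cfg)
        with pytest.raises(hl.SimulationFault):
            # queue far more diuresis than the stressed volume
            hl.plant_step(p, s, 0.0, 0.0, 100.0, dt=5.0)

    def test_infeasible_observation_is_flagged_fault(self, patient):
        s = hl.initial_plant_state(patient)
        bad = hl.PlantState(C=s.C, V_current=0.5, pending_diuresis=0.0,
                            S_L_current=s.S_L_current, HR_current=s.HR_current)
        with pytest.raises(hl.SimulationFault):
            _observe(patient, bad, t=3.0)


class TestClosedLoop:
    def test_zero_noise_converges_to_targets(self, zero_noise_run):
        df, tg = zero_noise_run.table, zero_noise_run.targets
        late = df[df.t >= 15.0 - 1e-9]
        assert np.all(np.abs(late.AP_true - tg.AP_star) < 2.0)
        assert np.all(np.abs(late.P_LA_true - tg.P_LA_star) < 1.0)

    def test_targets_follow_clinical_rule(self, zero_noise_run, patient):
        tg = zero_noise_run.targets
        assert tg.AP_star == pytest.approx(patient.baseline_state.AP - 10.0)
        assert tg.P_LA_star == pytest.approx(patient.baseline_state.P_LA)
        assert tg.AP_star >= 70.0 and tg.P_LA_star <= 18.0

    def test_ap_descends_monotonically_to_target(self, zero_noise_run):
        ap = zero_noise_run.table.AP_true.to_numpy()
        assert np.all(np.diff(ap) <= 1e-9)
        assert ap[0] == pytest.approx(87.0)

    def test_disabled_controllers_hold_baseline(self, patient):
        proto = hl.ProtocolConfig(
            duration=10.0, noise_enabled=False, Kp=0.0, Ki=0.0,
            volume=hl.VolumeControllerConfig(dextran_gain=0.0, dextran_max=0.0,
                                             furosemide_bolus=0.0),
        )
        df = hl.run_closed_loop(patient, proto, seed=0).table
        assert np.allclose(df.AP_true, patient.baseline_state.AP)
        assert np.allclose(df.P_LA_true, patient.baseline_state.P_LA)
        assert (df.landiolol_rate == 0).all()
        assert (df.dextran_rate == 0).all()
        assert (df.furosemide_bolus == 0).all()

    def test_identical_seed_identical_table(self, patient):
        proto = hl.ProtocolConfig(duration=10.0)
        df1 = hl.run_closed_loop(patient, proto, seed=5).table
        df2 = hl.run_closed_loop(patient, proto, seed=5).table
        pd.testing.assert_frame_equal(df1, df2, check_exact=True)

    def test_drug_rates_bounded_at_every_step(self, noisy_run):
        df = noisy_run.table
        proto = hl.ProtocolConfig()
        assert (df.landiolol_rate >= 0).all()
        assert (df.landiolol_rate <= proto.landiolol_max).all()
        assert (df.dextran_rate >= 0).all()
        assert (df.dextran_rate <= proto.volume.dextran_max).all()
        # dextran and furosemide never commanded together
        assert not ((df.dextran_rate > 0) & (df.furosemide_bolus > 0)).any()

    def test_row_grid_and_count(self, noisy_run):
        df = noisy_run.table
        assert len(df) == 361  # 60 min at 10-s steps, t=0 inclusive
        assert df.t.iloc[0] == 0.0
        assert df.t.iloc[-1] == 60.0
        assert (df.t >= 15.0).sum() == 271  # t=15 lands exactly on the grid
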