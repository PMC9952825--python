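"""Lumped valve model, analytic field, seeding and Lagrangian advection."""

import numpy as np
import pytest

from pvlkit import cli_io
from pvlkit.hemodynamics import (FluidProperties, PressureWaveform,
                                 segment_phases)
from pvlkit.synthetic_flow import (LeakChannel, SeedingPlan,
                                   SyntheticFlowField, SyntheticGeometry,
                                   ValveSchedule, advect, calibrate_schedule,
                                   reynolds_check, seed_particles,
                                   seeding_grid, synthetic_pressure_waveform)

T70 = 60 / 70


def _simple_geom(**kw):
    defaults = dict(leak_channels=[LeakChannel(azimuth=0.0, width=7e-3,
                                               height=5e-4, length=0.020)])
    defaults.update(kw)
    return SyntheticGeometry(**defaults)


def _square_dp():
    t = np.linspace(0, 0.857, 8001)
    dp = np.where(t % 0.857 < 0.21, 40.0, -85.0)
    dp[-1] = 40.0
    return PressureWaveform(t, dp, 0.857)


class TestPressureWaveform:
    def test_phase_averages_match_request(self):
        dp = synthetic_pressure_waveform(dp_sys_avg_mmhg=29.7,
                                         dp_dia_avg_mmhg=-86.6)
        seg = segment_phases(dp)
        tt = np.linspace(*seg.systole[0], 20001)
        assert np.trapezoid(dp(tt), tt) / 0.21 == pytest.approx(29.7,
                                                                rel=1e-3)
        lo, hi = seg.diastole[0]
        tt = np.linspace(lo, hi, 20001)
        assert np.trapezoid(dp(tt), tt) / (hi - lo) == pytest.approx(
            -86.6, rel=1e-3)

    def test_periodic_extension_continuous(self):
        dp = synthetic_pressure_waveform()
        assert dp(0.0) == pytest.approx(dp(dp.period), abs=1e-9)
        assert dp(0.05) == pytest.approx(dp(0.05 + 3 * dp.period), abs=1e-9)


class TestLumpedModel:
    def test_closed_valve_volume_below_tenth_ml(self, reduced_case):
        assert reduced_case.field.transvalvular_closed_volume() < 0.1

    def test_infinite_leak_resistance_removes_leak(self):
        dp = _square_dp()
        sched = ValveSchedule(r_valve_open=0.1, r_leak=1e12)
        field = SyntheticFlowField(dp, _simple_geom(), sched)
        assert field.branch_volumes()["leak"] == pytest.approx(0.0, abs=1e-6)

    def test_square_wave_leak_volume_hand_integration(self):
        # |−85| mmHg over 0.647 s through R_leak = 10 → 85/10·0.647 ≈ 5.50 mL
        dp = _square_dp()
        sched = ValveSchedule(r_valve_open=0.1, r_leak=10.0, ramp_s=1e-6)
        field = SyntheticFlowField(dp, _simple_geom(), sched)
        seg = segment_phases(dp)
        tt = np.linspace(*seg.diastole[0], 50001)
        v_dia = np.trapezoid(np.asarray(field.q_leak(tt)), tt)
        assert v_dia == pytest.approx(-5.50, abs=0.06)

    def test_branch_volumes_sum_to_waveform_integral(self, reduced_case):
        vols = reduced_case.field.branch_volumes()
        q = reduced_case.field.lumped_flow_waveform()
        net = np.trapezoid(q.q, q.t)
        assert vols["valve"] + vols["closing_pulse"] + vols["leak"] == \
            pytest.approx(net, rel=1e-6)

    def test_calibration_hits_leak_target(self):
        dp = synthetic_pressure_waveform(dp_sys_avg_mmhg=44.4,
                                         dp_dia_avg_mmhg=-86.8)
        sched = calibrate_schedule(dp, eoa_cm2=1.05, leak_ml=3.9,
                                   closing_ml=1.3)
        field = SyntheticFlowField(dp, _simple_geom(), sched)
        vols = field.branch_volumes()
        dia_leak = vols["leak"] - dp.period * 0  # leak branch net volume
        seg = segment_phases(dp)
        tt = np.linspace(*seg.diastole[0], 50001)
        v_dia = np.trapezoid(np.asarray(field.q_leak(tt)), tt)
        assert v_dia == pytest.approx(-3.9, rel=0.01)


class TestVelocityField:
    def test_channel_center_plane_poiseuille_peak(self, reduced_case):
        field = reduced_case.field
        geom = field.geometry
        ch = geom.leak_channels[0]
        seg = field.segmentation
        t_mid = 0.5 * sum(seg.diastole[0])
        rc = geom.lvot_radius - ch.offset
        center = np.array([[rc * np.cos(ch.azimuth),
                            rc * np.sin(ch.azimuth), 0.01]])
        u, grad = field.velocity(center, t_mid)
        qk = float(field.q_leak(t_mid)) * 1e-6 * ch.area \
            / geom.total_channel_area
        assert u[0, 2] == pytest.approx(1.5 * qk / ch.area, rel=1e-9)
        # centerline of the gap: zero cross-gap gradient
        assert grad[0, 2, 0] == pytest.approx(0.0, abs=1e-6)

    def test_channel_wall_no_slip(self, reduced_case):
        field = reduced_case.field
        geom = field.geometry
        ch = geom.leak_channels[0]
        t_mid = 0.5 * sum(field.segmentation.diastole[0])
        r_wall = geom.lvot_radius - ch.offset + ch.height / 2
        wall = np.array([[r_wall * np.cos(ch.azimuth),
                          r_wall * np.sin(ch.azimuth), 0.01]])
        u, _ = field.velocity(wall, t_mid)
        assert abs(u[0, 2]) < 1e-12

    def test_peak_diastolic_channel_velocity_regime(self, reduced_case):
        # default narrow-channel config reaches the ~4 m/s jet regime
        field = reduced_case.field
        geom = field.geometry
        ch = geom.leak_channels[0]
        seg = field.segmentation
        tt = np.linspace(*seg.diastole[0], 512)
        ql = np.abs(np.asarray(field.q_leak(tt))) * 1e-6
        upk = 1.5 * ql.max() * (ch.area / geom.total_channel_area) / ch.area
        assert upk == pytest.approx(4.0, rel=0.15)

    def test_divergence_free_in_lumen(self, reduced_case):
        # axial Poiseuille region: analytic gradient is traceless
        field = reduced_case.field
        rng = np.random.default_rng(2)
        pts = np.column_stack([rng.uniform(-5e-3, 5e-3, 20),
                               rng.uniform(-5e-3, 5e-3, 20),
                               rng.uniform(-0.035, -0.005, 20)])
        _, grad = field.velocity(pts, 0.1)
        np.testing.assert_allclose(np.trace(grad, axis1=1, axis2=2), 0.0,
                                   atol=1e-12)

    def test_outside_domain_zero_velocity(self, reduced_case):
        u, _ = reduced_case.field.velocity(np.array([[0, 0, 1.0]]), 0.1)
        assert np.all(u == 0)


class TestSeeding:
    def test_gauss_circle_count_at_paper_scale(self):
        # 1 cm disc at 200 µm spacing: 7845 grid points
        assert len(seeding_grid(1e-2, 200e-6)) == 7845

    def test_injection_step_count(self):
        plan = SeedingPlan(window_duration=0.210, cadence=5e-4)
        assert plan.n_steps == 420

    def test_degenerate_single_point(self):
        grid = seeding_grid(1e-3, 2e-3)
        assert grid.shape == (1, 2)
        np.testing.assert_array_equal(grid[0], [0.0, 0.0])

    def test_spacing_larger_than_lumen_errors(self):
        with pytest.raises(ValueError, match="larger than lumen"):
            seeding_grid(1e-3, 3e-3)

    def test_total_count_and_id_encoding(self):
        geom = _simple_geom()
        plan = SeedingPlan(spacing=5e-3, window_duration=0.02, cadence=1e-2)
        parts = seed_particles(plan, geom)
        n_grid = len(seeding_grid(geom.lvot_radius, 5e-3))
        assert len(parts) == 2 * n_grid
        assert parts[-1].id == 1 * n_grid + (n_grid - 1)


class TestAdvection:
    def test_zero_flow_keeps_particles_stationary(self):
        dp = _square_dp()
        sched = ValveSchedule(r_valve_open=1e9, r_leak=1e12,
                              r_valve_closed=1e12)
        geom = _simple_geom()
        field = SyntheticFlowField(dp, geom, sched, wash_frac=0.0)
        plan = SeedingPlan(spacing=5e-3, window_duration=0.01, cadence=0.01)
        parts = seed_particles(plan, geom)
        trajs = advect(parts, field, n_cycles=1, dt=5e-4, export_every=100)
        for tr in trajs:
            np.testing.assert_allclose(tr.pos, np.broadcast_to(
                tr.pos[0], tr.pos.shape), atol=1e-9)
            # residual SA from the ~1e-10 m/s numerical leak-through is
            # orders of magnitude below any physical accumulation
            assert tr.stress_accumulation() == pytest.approx(0.0, abs=1e-4)

    def test_rk4_halving_dt_reduces_error_fourth_order(self, reduced_case):
        # tracer in the sinus entrainment field during the steady diastolic
        # plateau: the velocity varies smoothly (exponentially) in space, so
        # the global error scales as dt^4
        field = reduced_case.field
        p0 = np.array([[8.5e-3 * np.cos(np.pi / 2 + 0.3),
                        8.5e-3 * np.sin(np.pi / 2 + 0.3), 0.010]])

        def integrate(dt, steps, t0=0.40):
            x = p0.copy()
            t = t0
            for _ in range(steps):
                k1, _ = field.velocity(x, t)
                k2, _ = field.velocity(x + 0.5 * dt * k1, t + 0.5 * dt)
                k3, _ = field.velocity(x + 0.5 * dt * k2, t + 0.5 * dt)
                k4, _ = field.velocity(x + dt * k3, t + dt)
                x = x + (dt / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
                t += dt
            return x

        ref = integrate(2.5e-4, 160)  # fine-step reference over 0.04 s
        errs = [np.linalg.norm(integrate(dt, n) - ref)
                for dt, n in [(4e-3, 10), (2e-3, 20), (1e-3, 40)]]
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders > 3.5)

    def test_inertial_mode_converges_to_tracer(self, reduced_case):
        geom = reduced_case.config.geometry
        plan = SeedingPlan(spacing=4e-3, window_duration=5e-4, cadence=5e-4)
        parts = seed_particles(plan, geom)
        tr = advect(parts, reduced_case.field, n_cycles=1, dt=5e-4,
                    export_every=50, mode="tracer")
        gaps = []
        for d in (3e-6, 3e-7):
            for p in parts:
                p.diameter = d
            inert = advect(parts, reduced_case.field, n_cycles=1, dt=5e-4,
                           export_every=50, mode="inertial")
            gap = max(np.abs(a.pos[-1] - b.pos[-1]).max()
                      for a, b in zip(tr, inert) if len(a) == len(b))
            gaps.append(gap)
        assert gaps[0] < 1e-5          # 3 µm platelets are near-tracers
        assert gaps[1] < gaps[0] + 1e-12

    def test_particle_conservation(self, reduced_cohort):
        particles, cohort = reduced_cohort
        statuses = [t.status for t in cohort]
        assert len(cohort) == len(particles)
        assert set(statuses) <= {"in_domain", "exited_aorta", "exited_inlet"}

    def test_determinism_identical_runs(self, reduced_case):
        geom = reduced_case.config.geometry
        plan = SeedingPlan(spacing=4e-3, window_duration=1e-3, cadence=1e-3)
        out = []
        for _ in range(2):
            parts = seed_particles(plan, geom, seed=11)
            trajs = advect(parts, reduced_case.field, n_cycles=1, dt=5e-4,
                           export_every=10, seed=11)
            out.append(np.concatenate([t.pos.ravel() for t in trajs]))
        np.testing.assert_array_equal(out[0], out[1])

    def test_invalid_arguments(self, reduced_case):
        with pytest.raises(ValueError):
            advect([], reduced_case.field, dt=0.0)
        with pytest.raises(ValueError):
            advect([], reduced_case.field, dt=1e-3)
        with pytest.raises(ValueError):
            advect([], reduced_case.field, n_cycles=0)


class TestReynolds:
    def test_hand_evaluation_from_samples(self):
        # Re = 1120·2·0.001/0.0035 = 640 for a 1 mm hydraulic diameter
        rho, u, dh, mu = 1120.0, 2.0, 1e-3, 3.5e-3
        assert rho * u * dh / mu == pytest.approx(640.0)

    def test_zero_flow_gives_zero(self):
        dp = _square_dp()
        sched = ValveSchedule(r_valve_open=0.1, r_leak=1e15)
        field = SyntheticFlowField(dp, _simple_geom(), sched)
        mean_re, max_re = reynolds_check(field)
        assert max_re < 1e-3

    def test_default_config_is_laminar(self, reduced_case):
        mean_re, max_re = reynolds_check(reduced_case.field)
        assert 0 < mean_re <= max_re < 2000
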