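"""Manufactured wave flows, the Womersley oracle, and the channel solver."""

import numpy as np
import pytest

import spinaldrift as sd
from spinaldrift.errors import ConvergenceError, InputError, ResolutionError


class TestManufacturedWave:
    def test_zero_amplitude_gives_zero_field(self):
        grid = sd.channel_grid(32, 8, 2.0, 0.25)
        f = sd.make_manufactured_wave_flow(grid, 0.0, np.pi, 1.0)
        assert np.all(f.u == 0) and np.all(f.v == 0)

    def test_standing_wave_cycle_mean_is_zero(self):
        grid = sd.channel_grid(64, 8, 2.0, 0.25)
        f = sd.make_manufactured_wave_flow(grid, 0.7, np.pi, 1.0, kind="standing")
        mean = sd.cycle_average(f)
        assert np.abs(mean.u).max() < 1e-13
        assert np.abs(mean.v).max() < 1e-13

    def test_discrete_divergence_vanishes(self, traveling_wave):
        assert traveling_wave.max_divergence() < 1e-12

    def test_under_resolved_wavelength_rejected(self):
        grid = sd.channel_grid(16, 8, 2.0, 0.25)   # 8 cells per wavelength
        with pytest.raises(ResolutionError):
            sd.make_manufactured_wave_flow(grid, 0.1, 2 * np.pi, 1.0)

    def test_traveling_wave_metadata_drift_is_u2k_over_2w(self, traveling_wave):
        U, k = 0.012, np.pi
        omega = 2 * np.pi
        assert traveling_wave.metadata["closed_form_drift_u"][0, 0] == pytest.approx(
            U**2 * k / (2 * omega)
        )


class TestWomersley:
    def test_flow_rate_reproduced_every_phase(self, small_channel):
        wf = sd.FlowRateWaveform.sinusoid(0.4, 1.0)
        f = sd.womersley_channel_flow(small_channel, wf, sd.FluidParams())
        assert f.metadata["max_flow_rate_error"] <= 5e-3

    def test_quasi_steady_limit_is_poiseuille(self):
        """For a slow oscillation the profile collapses to the parabola
        scaled to the instantaneous flow rate."""
        grid = sd.channel_grid(4, 64, 0.25, 0.3)
        wf = sd.FlowRateWaveform.sinusoid(0.4, 2000.0)
        fluid = sd.FluidParams(period=2000.0)
        f = sd.womersley_channel_flow(grid, wf, fluid, n_phases=8)
        y = grid.y_centers
        eta = (y - 0.15) / 0.15
        for k in range(8):
            q = wf(k * 2000.0 / 8)
            para = 1.5 * (q / 0.3) * (1 - eta**2)
            # tolerance scales with the waveform amplitude: the residual
            # oscillatory correction is O(alpha^2) of the amplitude
            assert np.abs(f.u[k, 0] - para).max() < 5e-3 * 0.4 / 0.3

    def test_zero_waveform_gives_zero_field(self, small_channel):
        wf = sd.FlowRateWaveform.sinusoid(0.0, 1.0)
        f = sd.womersley_channel_flow(small_channel, wf, sd.FluidParams())
        assert np.abs(f.u).max() == 0.0

    def test_multi_harmonic_rejected_or_decomposed(self, small_channel):
        t = np.arange(100) / 100
        q = np.sin(2 * np.pi * t) + 0.3 * np.sin(4 * np.pi * t)
        wf = sd.FlowRateWaveform(t, q, 1.0)
        with pytest.raises(InputError, match="harmonic"):
            sd.womersley_channel_flow(small_channel, wf, sd.FluidParams())
        f = sd.womersley_channel_flow(
            small_channel, wf, sd.FluidParams(), multi_harmonic="decompose"
        )
        assert f.metadata["max_flow_rate_error"] <= 5e-3

    def test_obstructed_grid_rejected(self):
        grid = sd.channel_grid(8, 16, 0.25, 0.3, wall_profile_bottom=lambda x: 0.05)
        with pytest.raises(InputError):
            sd.womersley_channel_flow(
                grid, sd.FlowRateWaveform.sinusoid(0.1, 1.0), sd.FluidParams()
            )


class TestOscillatorySolver:
    def test_zero_waveform_zero_velocity_zero_forcing(self, small_channel):
        wf = sd.FlowRateWaveform.sinusoid(0.0, 1.0)
        f, ctl = sd.solve_oscillatory_channel(
            small_channel, wf, sd.FluidParams(), dt=0.01
        )
        assert np.abs(f.u).max() == 0.0
        assert np.abs(ctl.forcing).max() == 0.0

    def test_flow_rate_tracking_and_error_norm_decay(self, small_channel):
        wf = sd.FlowRateWaveform.sinusoid(0.4, 1.0)
        f, ctl = sd.solve_oscillatory_channel(small_channel, wf, sd.FluidParams(), dt=0.005)
        # per-phase flow-rate match of the converged cycle
        q_num = f.u_face[:, 0, :].sum(axis=1) * small_channel.dy
        q_tgt = wf(f.phase_times)
        assert np.abs(q_num - q_tgt).max() / np.abs(q_tgt).max() <= 1e-2
        # controller error norm non-increasing over the final cycles
        tail = ctl.cycle_error_norms[-5:]
        assert all(b <= a * (1 + 1e-9) + 1e-14 for a, b in zip(tail, tail[1:]))

    def test_solver_matches_womersley_oracle(self, small_channel):
        """Obstacle-free solve agrees with the closed-form oscillatory
        profile to <=1% per-phase relative L2 at 64 transverse cells."""
        wf = sd.FlowRateWaveform.sinusoid(0.4, 1.0)
        fluid = sd.FluidParams()
        oracle = sd.womersley_channel_flow(small_channel, wf, fluid)
        f, _ = sd.solve_oscillatory_channel(small_channel, wf, fluid, dt=0.005)
        errs = [
            np.linalg.norm(f.u[k] - oracle.u[k]) / np.linalg.norm(oracle.u[k])
            for k in range(f.n_phases)
        ]
        assert max(errs) <= 1e-2

    def test_grid_refinement_reduces_oracle_error(self):
        """Halving the transverse spacing cuts the Womersley-oracle error by
        at least a factor 3 (second-order spatial scheme contract)."""
        wf = sd.FlowRateWaveform.sinusoid(0.4, 1.0)
        fluid = sd.FluidParams()
        errors = {}
        for ny in (16, 32):
            grid = sd.channel_grid(8, ny, 0.25, 0.3, axial_periodic=True)
            oracle = sd.womersley_channel_flow(grid, wf, fluid)
            f, _ = sd.solve_oscillatory_channel(grid, wf, fluid, dt=0.005)
            errors[ny] = max(
                np.linalg.norm(f.u[k] - oracle.u[k]) / np.linalg.norm(oracle.u[k])
                for k in range(f.n_phases)
            )
        assert errors[16] / errors[32] >= 3.0

    def test_nonconvergence_raises_with_history(self, small_channel):
        wf = sd.FlowRateWaveform.sinusoid(0.4, 1.0)
        with pytest.raises(ConvergenceError) as err:
            sd.solve_oscillatory_channel(
                small_channel, wf, sd.FluidParams(), dt=0.005,
                n_adjust_cycles=2, tol_periodic=1e-14, min_cycles=2,
            )
        assert len(err.value.history) >= 1

    def test_generated_fields_divergence_free(self, scenario_bundle):
        for key in ("field_obstructed", "field_patent"):
            field = scenario_bundle[key]
            u_ref = field.max_speed()
            tol = 1e-10 * u_ref / min(field.grid.dx, field.grid.dy)
            assert field.max_divergence() <= tol

    def test_obstacles_raise_forcing_amplitude(self, scenario_bundle):
        """Driving the same flow rate through the obstructed canal requires
        a strictly larger pressure-gradient amplitude than the patent one."""
        amp_o = scenario_bundle["controller_obstructed"].forcing_amplitude
        amp_p = scenario_bundle["controller_patent"].forcing_amplitude
        assert amp_o > amp_p

    def test_scenario_epsilon_is_physiological(self, scenario_bundle):
        grid = scenario_bundle["grid_obstructed"]
        _, eps = sd.stroke_volume_and_epsilon(
            scenario_bundle["waveform"], grid.fluid_volume()
        )
        assert eps == pytest.approx(0.439, abs=0.002)
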