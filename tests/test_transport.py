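"""Transport solvers, boundary/mass accounting and dispersion diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spinaldrift as sd
from spinaldrift.errors import ConservationError, InputError, StabilityError
from spinaldrift.fields import PeriodicVelocityField, SteadyVelocityField


def _grid(nx=64, ny=8, length=8.0, height=0.3, origin=(1.6, 0.0)):
    return sd.channel_grid(nx, ny, length, height, origin=origin, axial_periodic=True)


def _uniform_periodic(grid, u0=0.0, n_phases=4):
    nx, ny = grid.n_axial, grid.n_transverse
    u = np.full((n_phases, nx, ny), u0)
    v = np.zeros_like(u)
    uf = np.full((n_phases, nx + 1, ny), u0)
    vf = np.zeros((n_phases, nx, ny + 1))
    return PeriodicVelocityField(grid, 1.0, u, v, uf, vf)


def _steady_uniform(grid, u0, role="lagrangian_solenoidal"):
    nx, ny = grid.n_axial, grid.n_transverse
    return SteadyVelocityField(
        grid, np.full((nx, ny), u0), np.zeros((nx, ny)), role,
        np.full((nx + 1, ny), u0), np.zeros((nx, ny + 1)),
    )


class TestGaussianBolus:
    def test_peak_value_and_tail(self):
        grid = _grid().tile(1)
        c0 = sd.gaussian_bolus(grid, 5.6, 0.5)
        x = grid.x_centers
        k = np.argmin(np.abs(x - 5.6))
        assert c0.snapshots[0][k, 0] == pytest.approx(
            np.exp(-((x[k] - 5.6) ** 2) / 0.5)
        )
        assert c0.snapshots[0][0, 0] == pytest.approx(
            np.exp(-((x[0] - 5.6) ** 2) / 0.5)
        )

    def test_uniform_across_section_and_zero_in_solids(self):
        grid = sd.channel_grid(
            64, 16, 8.0, 0.3, origin=(1.6, 0.0),
            wall_profile_bottom=lambda x: np.where(abs(x - 5.0) < 0.3, 0.08, 0.0),
        ).tile(1)
        c0 = sd.gaussian_bolus(grid, 5.6, 0.5)
        c = c0.snapshots[0]
        assert c[grid.solid_mask].max() == 0.0
        fluid_col = c[10][grid.fluid_mask[10]]
        assert np.ptp(fluid_col) == 0.0

    def test_center_outside_domain_rejected(self):
        grid = _grid().tile(1)
        with pytest.raises(InputError):
            sd.gaussian_bolus(grid, 12.0, 0.5)


class TestFullTransport:
    def test_zero_velocity_zero_diffusion_is_identity(self):
        grid = _grid()
        f = _uniform_periodic(grid, 0.0)
        c0 = sd.gaussian_bolus(grid.tile(1), 5.6, 0.5)
        h = sd.integrate_full_transport(
            f, c0, sd.TransportParams(diffusivity=0.0, dt=0.01, t_end=1.0), 1
        )
        assert np.array_equal(h.snapshots[-1], h.snapshots[0])

    def test_pure_diffusion_variance_growth(self):
        """For zero flow, sigma^2(t) = sigma^2(0) + 2 kappa t (heat kernel)."""
        grid = _grid()
        f = _uniform_periodic(grid, 0.0)
        c0 = sd.gaussian_bolus(grid.tile(1), 5.6, 0.5)
        kappa = 2e-6  # m^2/s -> 0.02 cm^2/s
        h = sd.integrate_full_transport(
            f, c0, sd.TransportParams(diffusivity=kappa, dt=0.01, t_end=20.0), 1
        )
        met = sd.dispersion_stats(sd.longitudinal_profile(h))
        growth = met.table.sigma2.iloc[-1] - met.table.sigma2.iloc[0]
        assert growth == pytest.approx(2 * kappa * 1e4 * 20.0, rel=0.01)

    def test_steady_advection_translates_bolus(self):
        grid = _grid()
        f = _uniform_periodic(grid, 0.5)
        c0 = sd.gaussian_bolus(grid.tile(1), 4.0, 0.5)
        h = sd.integrate_full_transport(
            f, c0, sd.TransportParams(diffusivity=0.0, dt=0.01, t_end=4.0), 1
        )
        met = sd.dispersion_stats(sd.longitudinal_profile(h))
        shift = met.table.x_bar.iloc[-1] - met.table.x_bar.iloc[0]
        assert shift == pytest.approx(2.0, abs=0.02)
        # scheme dispersion error stays small
        assert met.table.sigma2.iloc[-1] == pytest.approx(
            met.table.sigma2.iloc[0], rel=0.05
        )

    def test_outflow_mass_goes_to_ledger(self):
        grid = _grid(nx=32, length=4.0, origin=(0.0, 0.0))
        f = _uniform_periodic(grid, 1.0)
        c0 = sd.gaussian_bolus(grid.tile(1), 3.5, 0.25)
        h = sd.integrate_full_transport(
            f, c0, sd.TransportParams(diffusivity=0.0, dt=0.01, t_end=2.0), 1
        )
        assert h.outflow_mass[-1] > 0.5 * h.initial_mass
        assert h.mass_closure_error() < 1e-6

    def test_cfl_violation_raises(self):
        grid = _grid()
        f = _uniform_periodic(grid, 20.0)
        c0 = sd.gaussian_bolus(grid.tile(1), 5.6, 0.5)
        with pytest.raises(StabilityError):
            sd.integrate_full_transport(
                f, c0, sd.TransportParams(diffusivity=0.0, dt=0.01, t_end=1.0), 1
            )

    def test_bounded_undershoot_invariant(self, scenario_bundle):
        for h in scenario_bundle["histories"].values():
            assert h.min_concentration() >= -1e-10


class TestReducedTransport:
    def test_zero_field_zero_kappa_identity(self):
        grid = _grid()
        vl = _steady_uniform(grid, 0.0)
        c0 = sd.gaussian_bolus(grid.tile(1), 5.6, 0.5)
        h = sd.integrate_reduced_transport(
            vl, c0, sd.TransportParams(diffusivity=0.0, dt=1.0, t_end=5.0), 1
        )
        assert np.array_equal(h.snapshots[-1], h.snapshots[0])

    def test_rejects_unprojected_lagrangian_field(self):
        grid = _grid()
        raw = _steady_uniform(grid, 0.1, role="lagrangian_raw")
        c0 = sd.gaussian_bolus(grid.tile(1), 5.6, 0.5)
        with pytest.raises(ConservationError, match="project"):
            sd.integrate_reduced_transport(
                raw, c0, sd.TransportParams(dt=1.0, t_end=5.0), 1
            )

    def test_eulerian_mean_run_is_labelled_comparison(self):
        grid = _grid()
        em = _steady_uniform(grid, 0.05, role="eulerian_mean")
        c0 = sd.gaussian_bolus(grid.tile(1), 5.6, 0.5)
        h = sd.integrate_reduced_transport(
            em, c0, sd.TransportParams(diffusivity=0.0, dt=1.0, t_end=2.0), 1
        )
        assert h.metadata["variant"] == "comparison_eulerian"

    def test_dt_auto_reduced_to_satisfy_cfl(self):
        grid = _grid()
        vl = _steady_uniform(grid, 0.5)   # CFL(dt=1) far above 1
        c0 = sd.gaussian_bolus(grid.tile(1), 5.6, 0.5)
        h = sd.integrate_reduced_transport(
            vl, c0, sd.TransportParams(diffusivity=0.0, dt=1.0, t_end=4.0), 1
        )
        assert h.metadata["dt_used"] < h.metadata["dt_requested"]

    def test_reduced_equals_full_for_steady_field(self):
        """With the same steady velocity the oscillatory and reduced solvers
        integrate the same equation: results agree to round-off at matched dt."""
        grid = _grid()
        u0 = 0.3
        f = _uniform_periodic(grid, u0)
        vl = _steady_uniform(grid, u0)
        c0 = sd.gaussian_bolus(grid.tile(1), 5.6, 0.5)
        pars = sd.TransportParams(diffusivity=0.0, dt=0.05, t_end=2.0)
        h_full = sd.integrate_full_transport(f, c0, pars, 1)
        h_red = sd.integrate_reduced_transport(vl, c0, pars, 1)
        assert np.abs(h_full.snapshots[-1] - h_red.snapshots[-1]).max() <= 1e-8


class TestDiagnostics:
    def test_profile_of_uniform_concentration_is_area(self):
        grid = sd.channel_grid(
            16, 16, 2.0, 0.3, origin=(0.0, 0.0),
            wall_profile_bottom=lambda x: np.where(np.abs(x - 1.0) < 0.3, 0.1, 0.0),
        ).tile(1)
        hist = sd.ConcentrationHistory(grid)
        hist.append(0.0, np.where(grid.fluid_mask, 2.0, 0.0), 0.0)
        prof = sd.longitudinal_profile(hist)
        assert np.allclose(prof.C[0], 2.0 * grid.open_area())

    def test_gaussian_profile_moments(self):
        """x_bar = centre and sigma = sqrt(width/2) for the canonical bolus
        profile C ~ exp[-(x-5.6)^2/0.5] on a wide domain."""
        x = np.linspace(0, 11.2, 2001)
        C = np.exp(-((x - 5.6) ** 2) / 0.5)
        prof = sd.LongitudinalProfile(x, np.array([0.0]), C[None, :])
        met = sd.dispersion_stats(prof)
        assert met.table.x_bar.iloc[0] == pytest.approx(5.6, abs=1e-9)
        assert np.sqrt(met.table.sigma2.iloc[0]) == pytest.approx(0.5, abs=1e-6)

    def test_symmetric_two_bump_profile_centre(self):
        x = np.linspace(0, 11.2, 1001)
        C = np.exp(-((x - 4.6) ** 2) / 0.3) + np.exp(-((x - 6.6) ** 2) / 0.3)
        met = sd.dispersion_stats(sd.LongitudinalProfile(x, np.array([0.0]), C[None, :]))
        assert met.table.x_bar.iloc[0] == pytest.approx(5.6, abs=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(shift=st.floats(-1.0, 1.0))
    def test_translation_shifts_mean_not_variance(self, shift):
        x = np.linspace(0, 14.0, 1400)
        C0 = np.exp(-((x - 6.0) ** 2) / 0.5)
        C1 = np.exp(-((x - 6.0 - shift) ** 2) / 0.5)
        prof = sd.LongitudinalProfile(x, np.array([0.0, 1.0]), np.stack([C0, C1]))
        met = sd.dispersion_stats(prof)
        assert met.table.x_bar.iloc[1] - met.table.x_bar.iloc[0] == pytest.approx(
            shift, abs=1e-6
        )
        assert met.table.sigma2.iloc[1] == pytest.approx(
            met.table.sigma2.iloc[0], abs=1e-6
        )

    def test_zero_mass_rejected(self):
        prof = sd.LongitudinalProfile(
            np.linspace(0, 1, 10), np.array([0.0]), np.zeros((1, 10))
        )
        with pytest.raises(InputError, match="zero"):
            sd.dispersion_stats(prof)

    def test_kappa_h_constant_variance_is_zero(self):
        tab = pd.DataFrame({"t": [0.0, 10.0, 20.0], "x_bar": 5.6, "sigma2": 0.25})
        met = sd.hydrodynamic_diffusivity(sd.DispersionMetrics(tab))
        assert met.table.kappa_H.iloc[1:].to_numpy() == pytest.approx(0.0)

    def test_kappa_h_recovers_molecular_diffusivity(self):
        kappa = 0.02  # cm^2/s
        t = np.array([0.0, 10.0, 30.0, 60.0])
        tab = pd.DataFrame({"t": t, "x_bar": 5.6, "sigma2": 0.25 + 2 * kappa * t})
        met = sd.hydrodynamic_diffusivity(sd.DispersionMetrics(tab))
        assert met.table.kappa_H.iloc[1:].to_numpy() == pytest.approx(kappa)

    def test_linear_interpolate_helper(self):
        assert sd.linear_interpolate(0.75, [0.5, 1.0], [1.0, 2.0]) == pytest.approx(1.5)
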