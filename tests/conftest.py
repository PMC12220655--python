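"""Shared fixtures.

The expensive end-to-end scenario computation (oscillatory flow solves for
the obstructed and patent channels, particle-tracked drift, projection, and
the four transport runs at 60 cycles) is performed once per session and
shared by the acceptance tests and the scenario-level property tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import spinaldrift as sd
from spinaldrift.scenarios import build_waveform, scenario_config


@pytest.fixture(scope="session")
def small_channel():
    """Obstacle-free periodic channel at the physiological SSAS gap."""
    return sd.channel_grid(8, 64, 0.25, 0.3, axial_periodic=True)


@pytest.fixture(scope="session")
def traveling_wave():
    """Manufactured traveling wave with closed-form Stokes drift."""
    grid = sd.channel_grid(128, 16, 2.0, 0.25, axial_periodic=True)
    return sd.make_manufactured_wave_flow(
        grid, amplitude=0.012, wavenumber=np.pi, period=1.0,
        kind="traveling", n_phases=200,
    )


def _drift_fields(field):
    particles = sd.lagrangian_mean_from_trajectories(field)
    raw = sd.scatter_to_grid(particles)
    solenoidal, potential = sd.project_solenoidal(raw)
    return particles, raw, solenoidal, potential


@pytest.fixture(scope="session")
def scenario_bundle():
    """Full desk-scale study: flow, drift and transport for both geometries."""
    fluid = sd.FluidParams()
    cfg_o = scenario_config("channel_obstructed")
    cfg_p = scenario_config("channel_patent")
    waveform = build_waveform(cfg_o)
    grid_o = cfg_o.geometry.build_grid()
    grid_p = cfg_p.geometry.build_grid()

    field_o, ctl_o = sd.solve_oscillatory_channel(
        grid_o, waveform, fluid, dt=cfg_o.flow.dt
    )
    field_p, ctl_p = sd.solve_oscillatory_channel(
        grid_p, waveform, fluid, dt=cfg_p.flow.dt
    )
    particles, raw, v_lagr, potential = _drift_fields(field_o)
    v_eul = sd.cycle_average(field_o)

    tgrid = grid_o.tile(cfg_o.geometry.n_segments)
    c0 = sd.gaussian_bolus(tgrid, 5.6, 0.5)
    c0_p = sd.gaussian_bolus(grid_p.tile(cfg_p.geometry.n_segments), 5.6, 0.5)
    full_pars = sd.TransportParams(
        diffusivity=cfg_o.transport.diffusivity,
        dt=cfg_o.transport.dt_full,
        scheme=cfg_o.transport.scheme_full,
        t_end=60.0,
    )
    red_pars = sd.TransportParams(
        diffusivity=cfg_o.transport.diffusivity,
        dt=cfg_o.transport.dt_reduced,
        scheme=cfg_o.transport.scheme_reduced,
        t_end=60.0,
    )

    hist = {
        "dns_obstructed": sd.integrate_full_transport(field_o, c0, full_pars, 8),
        "dns_obstructed_k0": sd.integrate_full_transport(
            field_o, c0,
            sd.TransportParams(
                diffusivity=0.0, dt=full_pars.dt, scheme=full_pars.scheme, t_end=60.0
            ),
            8,
        ),
        "dns_patent": sd.integrate_full_transport(field_p, c0_p, full_pars, 8),
        "reduced": sd.integrate_reduced_transport(v_lagr, c0, red_pars, 8),
        "eulerian": sd.integrate_reduced_transport(v_eul, c0, red_pars, 8),
    }
    metrics = {
        k: sd.hydrodynamic_diffusivity(
            sd.dispersion_stats(sd.longitudinal_profile(h))
        )
        for k, h in hist.items()
    }
    return {
        "waveform": waveform,
        "grid_obstructed": grid_o,
        "grid_patent": grid_p,
        "field_obstructed": field_o,
        "field_patent": field_p,
        "controller_obstructed": ctl_o,
        "controller_patent": ctl_p,
        "particles": particles,
        "v_raw": raw,
        "v_lagrangian": v_lagr,
        "v_eulerian": v_eul,
        "potential": potential,
        "histories": hist,
        "metrics": metrics,
    }


def sigma_at(metrics, t):
    tab = metrics.table
    k = int(np.argmin(np.abs(tab["t"].to_numpy() - t)))
    return float(np.sqrt(tab["sigma2"].iloc[k]))


def kappa_at(metrics, t):
    tab = metrics.table
    k = int(np.argmin(np.abs(tab["t"].to_numpy() - t)))
    return float(tab["kappa_H"].iloc[k])
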