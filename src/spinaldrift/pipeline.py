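"""End-to-end orchestration of the three-step reduced-order pipeline.

The hybrid three-step approach:

1. **flow** — compute the time-periodic Eulerian velocity field over one
   cycle (oscillatory Navier-Stokes solve with flow-rate control);
2. **drift** — evaluate the mean Lagrangian velocity from fluid-particle
   trajectories and project out its non-solenoidal component;
3. **transport** — integrate the reduced steady-advection equation on the
   long time scale (or, for benchmarking, the full oscillatory equation).

``run_pipeline`` executes the variant selected in the config end-to-end,
writes all artefacts to the output directory, and returns a manifest with
checksums of every intermediate (two runs of the same config produce
identical manifests: there is no randomness anywhere in the pipeline).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig
from .errors import InputError
from .fields import PeriodicVelocityField, SteadyVelocityField
from .flowfields import ControllerGains, solve_oscillatory_channel
from .helmholtz import project_solenoidal
from .lagrangian import cycle_average, lagrangian_mean_from_trajectories, scatter_to_grid
from .scenarios import build_waveform
from .transport import (
    TransportParams,
    dispersion_stats,
    gaussian_bolus,
    hydrodynamic_diffusivity,
    integrate_full_transport,
    integrate_reduced_transport,
    longitudinal_profile,
)
from .waveforms import stroke_volume_and_epsilon


def _checksum(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a, dtype=np.float64).tobytes())
    return h.hexdigest()[:16]


def run_flow_stage(config: PipelineConfig):
    """Step 1: periodic velocity field + controller trace."""
    grid = config.geometry.build_grid()
    waveform = build_waveform(config)
    fluid = config.fluid.build()
    gains = ControllerGains(
        config.flow.proportional, config.flow.integral, config.flow.derivative
    )
    field, controller = solve_oscillatory_channel(
        grid,
        waveform,
        fluid,
        gains=gains,
        n_adjust_cycles=config.flow.n_adjust_cycles,
        dt=config.flow.dt,
        n_store=config.flow.n_store,
        tol_periodic=config.flow.tol_periodic,
    )
    return field, controller, waveform


def run_drift_stage(config: PipelineConfig, field: PeriodicVelocityField):
    """Step 2: trajectory-based mean Lagrangian velocity, projected."""
    phases = np.arange(config.drift.n_phases) * field.period / config.drift.n_phases
    particles = lagrangian_mean_from_trajectories(
        field, phases=phases, substeps_per_cycle=config.drift.substeps_per_cycle
    )
    raw = scatter_to_grid(particles)
    solenoidal, potential = project_solenoidal(raw)
    return particles, raw, solenoidal, potential


def run_transport_stage(
    config: PipelineConfig,
    field: PeriodicVelocityField | None = None,
    mean_field: SteadyVelocityField | None = None,
):
    """Step 3: transport under the selected variant."""
    tc = config.transport
    base_grid = (field or mean_field).grid
    grid = base_grid.tile(config.geometry.n_segments) if base_grid.axial_periodic else base_grid
    c0 = gaussian_bolus(grid, tc.bolus_center, tc.bolus_width)
    if config.variant in ("full_dns", "diffusionless"):
        if field is None:
            raise InputError("full transport needs the periodic velocity field")
        params = TransportParams(
            diffusivity=0.0 if config.variant == "diffusionless" else tc.diffusivity,
            dt=tc.dt_full,
            scheme=tc.scheme_full,
            t_end=tc.t_end,
            snapshot_interval=tc.snapshot_interval,
        )
        return integrate_full_transport(
            field, c0, params, n_segments=config.geometry.n_segments
        )
    if mean_field is None:
        raise InputError("reduced transport needs a steady mean field")
    params = TransportParams(
        diffusivity=tc.diffusivity,
        dt=tc.dt_reduced,
        scheme=tc.scheme_reduced,
        t_end=tc.t_end,
        snapshot_interval=tc.snapshot_interval,
    )
    return integrate_reduced_transport(
        mean_field, c0, params, n_segments=config.geometry.n_segments
    )


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Execute the configured variant end-to-end; returns the run manifest."""
    from . import io as fio

    out = Path(config.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    field, controller, waveform = run_flow_stage(config)
    v_ref = config.geometry.build_grid().fluid_volume()
    # eps is defined against the obstructed reference volume via the
    # waveform; report it against this run's own geometry too.
    v_s, eps_own = stroke_volume_and_epsilon(waveform, v_ref)

    manifest: dict = {
        "package_version": __version__,
        "scenario": config.scenario,
        "variant": config.variant,
        "config": config.to_dict(),
        "stroke_volume_mL": v_s,
        "epsilon_vs_own_volume": eps_own,
        "flow": {
            "n_cycles": controller.n_cycles,
            "periodicity_residual": controller.periodicity_residuals[-1],
            "cycle_error_norms": controller.cycle_error_norms[-5:],
            "forcing_amplitude_cm_s2": controller.forcing_amplitude,
            "pressure_amplitude_Pa": controller.pressure_amplitude,
            "checksum": _checksum(field.u, field.v),
        },
    }

    mean_field = None
    if config.variant == "lagrangian":
        particles, raw, mean_field, potential = run_drift_stage(config, field)
        counts = particles.table["status"].value_counts().to_dict()
        manifest["drift"] = {
            "particle_status_counts": {k: int(v) for k, v in counts.items()},
            "max_div_before": mean_field.metadata["max_div_before"],
            "max_div_after": mean_field.metadata["max_div_after"],
            "checksum": _checksum(mean_field.u, mean_field.v),
        }
        if write:
            particles.to_csv(out / "particles.csv")
            fio.write_steady_field(raw, out / "v_lagrangian_raw.nc")
            fio.write_steady_field(mean_field, out / "v_lagrangian.nc")
    elif config.variant == "eulerian_mean":
        mean_field = cycle_average(field)
        manifest["drift"] = {
            "method": "eulerian_mean",
            "checksum": _checksum(mean_field.u, mean_field.v),
        }
        if write:
            fio.write_steady_field(mean_field, out / "v_eulerian_mean.nc")

    history = run_transport_stage(config, field=field, mean_field=mean_field)
    profile = longitudinal_profile(history)
    metrics = hydrodynamic_diffusivity(dispersion_stats(profile))
    metrics.stroke_volume = v_s
    metrics.epsilon = eps_own
    final = metrics.table.iloc[-1]
    manifest["transport"] = {
        "variant_label": history.metadata["variant"],
        "scheme": history.metadata["scheme"],
        "dt": history.metadata["dt"],
        "dt_requested": history.metadata.get("dt_requested"),
        "mass_closure_error": history.mass_closure_error(),
        "final_time": float(history.times[-1]),
        "x_bar_final_cm": float(final["x_bar"]),
        "sigma_final_cm": float(np.sqrt(final["sigma2"])),
        "kappa_H_final_cm2_s": float(final["kappa_H"]),
        "checksum": _checksum(history.snapshots[-1]),
    }

    if write:
        fio.write_periodic_field(field, out / "velocity_cycle.nc")
        fio.write_waveform_csv(waveform, out / "waveform.csv")
        fio.write_metrics_csv(metrics, out / "metrics.csv")
        fio.write_metrics_json(metrics, out / "metrics.json")
        np.savetxt(
            out / "profile_final.csv",
            np.column_stack([profile.x, profile.C[-1]]),
            delimiter=",",
            header="x_cm,C_cm2",
            comments="",
        )
        fio.write_manifest(manifest, out / "manifest.json")
    manifest["_objects"] = {
        "field": field,
        "mean_field": mean_field,
        "history": history,
        "profile": profile,
        "metrics": metrics,
        "controller": controller,
    }
    return manifest
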