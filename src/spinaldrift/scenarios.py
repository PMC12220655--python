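"""Canonical desk-scale scenarios and ready-to-run fixtures.

The study conditions emulate oscillatory CSF flow in the cervical canal at
physiological dimensionless stroke length: a 2-D channel with a 0.6 cm gap
(the scale of the subarachnoid space), a 1.0 cm repeating segment tiled
eight times across the transport domain x in [1.6, 9.6] cm, cardiac period
T = 1 s, CSF viscosity nu = 0.7e-6 m^2/s, drug Schmidt number 1000, and a
sinusoidal flow-rate waveform whose stroke volume gives eps = V_s/V_segment
= 0.439.  The "obstructed" geometry carries two staggered smooth wall bumps
per segment (stand-ins for nerve-rootlet bundles and denticulate-ligament
attachments, whose spacing is comparable to the stroke length); the
"patent" geometry is the bare channel, driven by the *same* waveform so the
isolated effect of the obstacles on dispersion can be measured.
"""

from __future__ import annotations

from pathlib import Path

from .config import (
    GeometryConfig,
    ObstacleConfig,
    PipelineConfig,
    TransportConfig,
    WaveformConfig,
)
from .errors import InputError

#: dimensionless stroke length of the physiological waveform
EPSILON_PHYSIOLOGICAL = 0.439
#: flow-rate reduction factor for the small-stroke validation regime
SMALL_STROKE_FACTOR = 0.00763

_OBSTACLES = [
    ObstacleConfig(side="bottom", center_frac=0.32, height=0.10, halfwidth=0.30),
    ObstacleConfig(side="top", center_frac=0.68, height=0.10, halfwidth=0.30),
]


def scenario_config(
    name: str,
    variant: str = "lagrangian",
    output_dir: str | None = None,
    t_end: float = 60.0,
) -> PipelineConfig:
    """Pipeline configuration for a named scenario.

    ``channel_obstructed`` / ``channel_patent`` are the two benchmark
    geometries; ``*_small_stroke`` variants scale the waveform by the
    small-stroke factor 0.00763 used to validate the asymptotic drift.
    """
    base = name.replace("_small_stroke", "")
    if base not in ("channel_obstructed", "channel_patent"):
        raise InputError(f"unknown scenario {name!r}")
    obstacles = list(_OBSTACLES) if base == "channel_obstructed" else []
    scale = SMALL_STROKE_FACTOR if name.endswith("_small_stroke") else 1.0
    cfg = PipelineConfig(
        scenario=name,
        variant=variant,
        output_dir=output_dir or f"runs/{name}_{variant}",
        geometry=GeometryConfig(obstacles=obstacles),
        waveform=WaveformConfig(epsilon=EPSILON_PHYSIOLOGICAL, scale=scale),
        transport=TransportConfig(t_end=t_end),
    )
    return cfg


def reference_segment_volume() -> float:
    """Fluid volume (mL) of the obstructed reference segment.

    The stroke length eps is defined against the obstructed geometry's
    segment volume (the analogue of the vertebral-segment CSF volume), for
    the patent scenario as well — both scenarios share one waveform.
    """
    return scenario_config("channel_obstructed").geometry.build_grid().fluid_volume()


def build_waveform(cfg: PipelineConfig):
    """The scenario waveform (always referenced to the obstructed volume)."""
    return cfg.waveform.build(reference_segment_volume())


def make_fixtures(kind: str, directory) -> list[Path]:
    """Write ready-to-run configs (and oracle fields for analytic kinds).

    Returns the list of files written.  ``manufactured`` also stores the
    analytic wave field whose metadata carries the closed-form drift;
    ``womersley`` stores the exact oscillatory channel solution.
    """
    from .flowfields import make_manufactured_wave_flow, womersley_channel_flow
    from .grid import channel_grid
    from .io import write_periodic_field, write_waveform_csv
    from .waveforms import FlowRateWaveform, FluidParams

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if kind in ("channel_patent", "channel_obstructed"):
        cfg = scenario_config(kind)
        path = directory / f"{kind}.yaml"
        cfg.to_yaml(path)
        written.append(path)
        wf_path = directory / "waveform.csv"
        write_waveform_csv(build_waveform(cfg), wf_path)
        written.append(wf_path)
    elif kind == "womersley":
        cfg = scenario_config("channel_patent")
        path = directory / "womersley.yaml"
        cfg.to_yaml(path)
        written.append(path)
        grid = cfg.geometry.build_grid()
        wf = build_waveform(cfg)
        field = womersley_channel_flow(grid, wf, cfg.fluid.build())
        field.metadata["configured_amplitude"] = float(wf.flow_rate.max())
        nc = directory / "womersley_oracle.nc"
        write_periodic_field(field, nc)
        written.append(nc)
        wf_path = directory / "waveform.csv"
        write_waveform_csv(wf, wf_path)
        written.append(wf_path)
    elif kind == "manufactured":
        grid = channel_grid(128, 16, 2.0, 0.25, axial_periodic=True)
        field = make_manufactured_wave_flow(
            grid, amplitude=0.03, wavenumber=2 * 3.141592653589793 / 2.0,
            period=1.0, kind="traveling", n_phases=100,
        )
        nc = directory / "manufactured_wave.nc"
        write_periodic_field(field, nc)
        written.append(nc)
    else:
        raise InputError(f"unknown fixture kind {kind!r}")
    return written
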