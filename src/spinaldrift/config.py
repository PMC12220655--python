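"""Pipeline configuration: nested dataclasses with YAML round-trip.

A :class:`PipelineConfig` fully determines a run (the pipeline contains no
randomness), and round-trips through ``to_dict``/``from_dict`` and YAML
unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import InputError
from .grid import StructuredGrid, channel_grid
from .waveforms import FluidParams, FlowRateWaveform

VARIANTS = ("lagrangian", "eulerian_mean", "diffusionless", "full_dns")


@dataclass
class ObstacleConfig:
    """A smooth wall bump (compact-support cosine-squared profile).

    ``side`` is ``"bottom"`` or ``"top"``; ``center_frac`` the bump centre as
    a fraction of the segment length; ``height``/``halfwidth`` in cm.  The
    bump intrudes into the channel like a nerve-rootlet bundle or denticulate
    ligament attachment, while keeping wall slopes (and hence transverse
    velocities) bounded on the stair-step mask.
    """

    side: str = "bottom"
    center_frac: float = 0.32
    height: float = 0.10
    halfwidth: float = 0.30


@dataclass
class GeometryConfig:
    height: float = 0.6            # channel gap, cm
    segment_length: float = 1.0    # repeating-segment length, cm
    n_axial: int = 32
    n_transverse: int = 64
    origin_x: float = 1.6          # rostral end of the transport domain, cm
    n_segments: int = 8            # replication count for transport
    obstacles: list = field(default_factory=list)

    def build_grid(self) -> StructuredGrid:
        def profile(side):
            bumps = [o for o in self.obstacles if o.side == side]
            if not bumps:
                return None

            def h(x):
                xl = (x - self.origin_x) % self.segment_length
                out = np.zeros_like(np.asarray(xl, dtype=float))
                for b in bumps:
                    d = xl - b.center_frac * self.segment_length
                    inside = np.abs(d) < b.halfwidth
                    out = out + np.where(
                        inside,
                        b.height * np.cos(np.pi * d / (2 * b.halfwidth)) ** 2,
                        0.0,
                    )
                return out

            return h

        return channel_grid(
            self.n_axial,
            self.n_transverse,
            self.segment_length,
            self.height,
            origin=(self.origin_x, 0.0),
            wall_profile_bottom=profile("bottom"),
            wall_profile_top=profile("top"),
            axial_periodic=True,
            n_segments=self.n_segments,
        )


@dataclass
class WaveformConfig:
    """Flow-rate waveform: an analytic sinusoid or a 2-column CSV file.

    With ``kind="sinusoid"`` either ``amplitude`` (mL/s) is given directly
    or ``epsilon`` sets it so the stroke volume is ``epsilon`` times the
    segment fluid volume (V_s = Q0 T / pi for a sinusoid).
    """

    kind: str = "sinusoid"
    amplitude: float | None = None
    epsilon: float | None = 0.439
    period: float = 1.0
    n_samples: int = 100
    scale: float = 1.0
    csv_path: str | None = None

    def build(self, reference_volume: float) -> FlowRateWaveform:
        from .io import read_waveform_csv

        if self.kind == "csv":
            if not self.csv_path or not Path(self.csv_path).exists():
                raise InputError(f"waveform CSV not found: {self.csv_path}")
            wf = read_waveform_csv(self.csv_path, period=self.period)
        elif self.kind == "sinusoid":
            if self.amplitude is not None:
                q0 = self.amplitude
            elif self.epsilon is not None:
                q0 = self.epsilon * np.pi * reference_volume / self.period
            else:
                raise InputError("sinusoid waveform needs amplitude or epsilon")
            wf = FlowRateWaveform.sinusoid(q0, self.period, self.n_samples)
        else:
            raise InputError(f"unknown waveform kind {self.kind!r}")
        return wf.scaled(self.scale) if self.scale != 1.0 else wf


@dataclass
class FluidConfig:
    density: float = 1000.0           # kg/m^3
    kinematic_viscosity: float = 0.7e-6  # m^2/s
    period: float = 1.0               # s

    def build(self) -> FluidParams:
        return FluidParams(self.density, self.kinematic_viscosity, self.period)


@dataclass
class FlowSolverConfig:
    dt: float = 0.005
    n_adjust_cycles: int = 100
    tol_periodic: float = 1e-4
    n_store: int = 100
    proportional: float = 1.0
    integral: float = 0.0
    derivative: float = 0.0


@dataclass
class DriftConfig:
    n_phases: int = 20
    substeps_per_cycle: int | None = None


@dataclass
class TransportConfig:
    diffusivity: float = 7e-10     # m^2/s (Schmidt number 1000 in CSF)
    # 0.005 s keeps the cellwise advective CFL sum of the physiological-eps
    # obstructed flow below 1 on the 256 x 64 transport grid
    dt_full: float = 0.005
    dt_reduced: float = 1.0
    t_end: float = 60.0
    scheme_full: str = "limited_upwind_3rd"
    scheme_reduced: str = "upwind_2nd"
    snapshot_interval: float = 1.0
    bolus_center: float = 5.6
    bolus_width: float = 0.5


@dataclass
class PipelineConfig:
    scenario: str = "channel_obstructed"
    variant: str = "lagrangian"
    output_dir: str = "runs/out"
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    waveform: WaveformConfig = field(default_factory=WaveformConfig)
    fluid: FluidConfig = field(default_factory=FluidConfig)
    flow: FlowSolverConfig = field(default_factory=FlowSolverConfig)
    drift: DriftConfig = field(default_factory=DriftConfig)
    transport: TransportConfig = field(default_factory=TransportConfig)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise InputError(f"variant must be one of {VARIANTS}")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        geo = dict(d.get("geometry", {}))
        geo["obstacles"] = [ObstacleConfig(**o) for o in geo.get("obstacles", [])]
        return cls(
            scenario=d.get("scenario", "channel_obstructed"),
            variant=d.get("variant", "lagrangian"),
            output_dir=d.get("output_dir", "runs/out"),
            geometry=GeometryConfig(**geo),
            waveform=WaveformConfig(**d.get("waveform", {})),
            fluid=FluidConfig(**d.get("fluid", {})),
            flow=FlowSolverConfig(**d.get("flow", {})),
            drift=DriftConfig(**d.get("drift", {})),
            transport=TransportConfig(**d.get("transport", {})),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
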