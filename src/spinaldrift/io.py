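"""Shared file I/O: NetCDF fields, CSV waveforms/metrics, JSON manifests.

Dialect: fields are written as NetCDF (classic format via the scipy
backend) with variables ``u``/``v`` (cm/s) on dims ``(phase, x, y)`` or
``(x, y)``, staggered companions ``u_face``/``v_face`` when present, an
integer ``mask`` variable (1 = solid), and grid geometry in attributes.
Waveforms are 2-column CSV ``t_s, Q_mL_per_s`` with the period recorded in
a leading comment line.  All round-trips are lossless to float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .errors import InputError
from .fields import PeriodicVelocityField, SteadyVelocityField
from .grid import StructuredGrid
from .transport import DispersionMetrics
from .waveforms import FlowRateWaveform

_ENGINE = "scipy"


def _grid_attrs(grid: StructuredGrid) -> dict:
    return {
        "dx": grid.dx,
        "dy": grid.dy,
        "origin_x": grid.origin[0],
        "origin_y": grid.origin[1],
        "axial_periodic": int(grid.axial_periodic),
        "n_segments": grid.n_segments,
        "units_velocity": "cm/s",
        "units_length": "cm",
    }


def _grid_from_attrs(attrs: dict, mask: np.ndarray) -> StructuredGrid:
    return StructuredGrid(
        n_axial=mask.shape[0],
        n_transverse=mask.shape[1],
        dx=float(attrs["dx"]),
        dy=float(attrs["dy"]),
        origin=(float(attrs["origin_x"]), float(attrs["origin_y"])),
        solid_mask=mask.astype(bool),
        axial_periodic=bool(int(attrs["axial_periodic"])),
        n_segments=int(attrs["n_segments"]),
    )


def write_periodic_field(field: PeriodicVelocityField, path) -> None:
    data = {
        "u": (("phase", "x", "y"), field.u),
        "v": (("phase", "x", "y"), field.v),
        "mask": (("x", "y"), field.grid.solid_mask.astype(np.int8)),
    }
    if field.has_faces:
        data["u_face"] = (("phase", "xf", "y"), field.u_face)
        data["v_face"] = (("phase", "x", "yf"), field.v_face)
    ds = xr.Dataset(
        data,
        coords={"phase_time": ("phase", field.phase_times)},
        attrs={**_grid_attrs(field.grid), "period": field.period},
    )
    for key, val in field.metadata.items():
        if isinstance(val, np.ndarray) and val.shape == field.u.shape[1:]:
            ds[f"meta_{key}"] = (("x", "y"), val.astype(float))
        elif isinstance(val, (int, float, str, bool)):
            ds.attrs[f"meta_{key}"] = val
    ds.to_netcdf(path, engine=_ENGINE)


def read_periodic_field(path) -> PeriodicVelocityField:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    grid = _grid_from_attrs(ds.attrs, ds["mask"].to_numpy())
    meta = {k[5:]: v for k, v in ds.attrs.items() if k.startswith("meta_")}
    for name in ds.data_vars:
        if name.startswith("meta_"):
            meta[name[5:]] = ds[name].to_numpy()
    return PeriodicVelocityField(
        grid,
        float(ds.attrs["period"]),
        ds["u"].to_numpy(),
        ds["v"].to_numpy(),
        ds["u_face"].to_numpy() if "u_face" in ds else None,
        ds["v_face"].to_numpy() if "v_face" in ds else None,
        meta,
    )


def write_steady_field(field: SteadyVelocityField, path) -> None:
    data = {
        "u": (("x", "y"), field.u),
        "v": (("x", "y"), field.v),
        "mask": (("x", "y"), field.grid.solid_mask.astype(np.int8)),
    }
    if field.has_faces:
        data["u_face"] = (("xf", "y"), field.u_face)
        data["v_face"] = (("x", "yf"), field.v_face)
    ds = xr.Dataset(data, attrs={**_grid_attrs(field.grid), "role": field.role})
    for key, val in field.metadata.items():
        if isinstance(val, np.ndarray) and val.shape == field.u.shape:
            ds[f"meta_{key}"] = (("x", "y"), val.astype(float))
        elif isinstance(val, (int, float, str, bool)):
            ds.attrs[f"meta_{key}"] = val
    ds.to_netcdf(path, engine=_ENGINE)


def read_steady_field(path) -> SteadyVelocityField:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    grid = _grid_from_attrs(ds.attrs, ds["mask"].to_numpy())
    meta = {k[5:]: v for k, v in ds.attrs.items() if k.startswith("meta_")}
    for name in ds.data_vars:
        if name.startswith("meta_"):
            meta[name[5:]] = ds[name].to_numpy()
    return SteadyVelocityField(
        grid,
        ds["u"].to_numpy(),
        ds["v"].to_numpy(),
        str(ds.attrs["role"]),
        ds["u_face"].to_numpy() if "u_face" in ds else None,
        ds["v_face"].to_numpy() if "v_face" in ds else None,
        meta,
    )


# ---------------------------------------------------------------------------
# waveforms

def write_waveform_csv(waveform: FlowRateWaveform, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# period_s = {float(waveform.period)!r}\n")
        fh.write("t_s,Q_mL_per_s\n")
        for t, q in zip(waveform.times, waveform.flow_rate):
            fh.write(f"{float(t)!r},{float(q)!r}\n")


def read_waveform_csv(path, period: float | None = None) -> FlowRateWaveform:
    path = Path(path)
    first = path.read_text().splitlines()[0]
    if first.startswith("#") and "period_s" in first:
        period = float(first.split("=")[1])
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.shape[1] < 2:
        raise InputError("waveform CSV needs two columns (t_s, Q_mL_per_s)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    q = df.iloc[:, 1].to_numpy(dtype=float)
    if period is None:
        period = float(t[-1] + (t[1] - t[0] if t.size > 1 else 1.0))
    return FlowRateWaveform(t, q, period)


# ---------------------------------------------------------------------------
# metrics

def write_metrics_csv(metrics: DispersionMetrics, path) -> None:
    metrics.table.to_csv(path, index=False)


def write_metrics_json(metrics: DispersionMetrics, path) -> None:
    payload = {
        "table": metrics.table.to_dict(orient="list"),
        "stroke_volume": metrics.stroke_volume,
        "epsilon": metrics.epsilon,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_metrics_json(path) -> DispersionMetrics:
    payload = json.loads(Path(path).read_text())
    return DispersionMetrics(
        pd.DataFrame(payload["table"]),
        payload.get("stroke_volume"),
        payload.get("epsilon"),
    )


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
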