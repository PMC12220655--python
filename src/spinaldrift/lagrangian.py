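"""Mean Lagrangian velocity of a time-periodic flow, two ways.

In a purely oscillatory but spatially non-uniform flow, fluid particles do
not return to their starting point after one cycle: the cycle-averaged
Eulerian velocity <v> misses the kinematic Stokes drift.  For small
dimensionless stroke length eps the mean Lagrangian velocity is

    v_L = <v> + < (int (v - <v>) dt) . grad (v - <v>) >,

while for finite eps it must be measured from particle trajectories: a
particle seeded at x_i at phase t_i is advected for one period, its cycle
displacement delta_x = x_p(t_i + T) - x_i and cycle-mean position
x_o = (1/T) int x_p dt are recorded, and v*_L(x_o) = delta_x / T.  Samples
from several seeding phases are deposited on the grid and averaged.

The trajectory-based v*_L is generally not divergence-free; the Helmholtz
projection (``spinaldrift.helmholtz``) removes its potential part before it
is used for transport.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator, griddata

from .errors import InputError
from .fields import PeriodicVelocityField, SteadyVelocityField
from .grid import StructuredGrid

STATUS_OK = "ok"
STATUS_SOLID = "entered_solid"
STATUS_LEFT = "left_domain"


# ---------------------------------------------------------------------------
# Eulerian cycle statistics

def cycle_average(field: PeriodicVelocityField) -> SteadyVelocityField:
    """Cycle-averaged (streaming) Eulerian velocity <v>.

    With equally spaced snapshots of a periodic signal the trapezoidal rule
    with periodic closure reduces to the plain snapshot mean.
    """
    if field.n_phases < 2:
        raise InputError("cycle averaging needs at least two phase snapshots")
    uf = vf = None
    if field.has_faces:
        uf = field.u_face.mean(axis=0)
        vf = field.v_face.mean(axis=0)
    return SteadyVelocityField(
        field.grid, field.u.mean(axis=0), field.v.mean(axis=0),
        "eulerian_mean", uf, vf,
    )


def _masked_gradient(f: np.ndarray, grid: StructuredGrid):
    """(df/dx, df/dy) with centred differences, one-sided next to solids.

    Returns the two derivative arrays and a flag array marking cells where a
    one-sided stencil was used.
    """
    fm = grid.fluid_mask
    dx, dy = grid.dx, grid.dy

    if grid.axial_periodic:
        f_l, f_r = np.roll(f, 1, axis=0), np.roll(f, -1, axis=0)
        ok_l, ok_r = np.roll(fm, 1, axis=0), np.roll(fm, -1, axis=0)
    else:
        f_l = np.vstack([f[:1], f[:-1]])
        f_r = np.vstack([f[1:], f[-1:]])
        ok_l = np.vstack([np.zeros((1, f.shape[1]), bool), fm[:-1]])
        ok_r = np.vstack([fm[1:], np.zeros((1, f.shape[1]), bool)])
    dfdx = np.where(
        ok_l & ok_r, (f_r - f_l) / (2 * dx),
        np.where(ok_r, (f_r - f) / dx, np.where(ok_l, (f - f_l) / dx, 0.0)),
    )

    f_d = np.hstack([f[:, :1], f[:, :-1]])
    f_u = np.hstack([f[:, 1:], f[:, -1:]])
    ok_d = np.hstack([np.zeros((f.shape[0], 1), bool), fm[:, :-1]])
    ok_u = np.hstack([fm[:, 1:], np.zeros((f.shape[0], 1), bool)])
    dfdy = np.where(
        ok_d & ok_u, (f_u - f_d) / (2 * dy),
        np.where(ok_u, (f_u - f) / dy, np.where(ok_d, (f - f_d) / dy, 0.0)),
    )
    one_sided = fm & ~(ok_l & ok_r & ok_d & ok_u)
    dfdx = np.where(fm, dfdx, 0.0)
    dfdy = np.where(fm, dfdy, 0.0)
    return dfdx, dfdy, one_sided


def stokes_drift_asymptotic(field: PeriodicVelocityField) -> SteadyVelocityField:
    """Small-stroke Stokes drift < (int v' dt) . grad v' > per cell.

    v' = v - <v> is the purely oscillatory velocity; its zero-mean time
    antiderivative (the particle excursion) is contracted with the v'
    gradient and cycle-averaged.  Cells where the gradient stencil had to
    fall back to one-sided differences next to solids are flagged in the
    metadata.
    """
    if field.n_phases < 2:
        raise InputError("Stokes drift needs at least two phase snapshots")
    grid = field.grid
    n = field.n_phases
    dt = field.period / n
    up = field.u - field.u.mean(axis=0)
    vp = field.v - field.v.mean(axis=0)

    def excursion(fp):
        # cumulative trapezoid over the periodic cycle, zero-mean gauge
        mid = 0.5 * (fp + np.roll(fp, -1, axis=0)) * dt
        xi = np.concatenate([np.zeros_like(fp[:1]), np.cumsum(mid, axis=0)[:-1]])
        return xi - xi.mean(axis=0)

    xi_x = excursion(up)
    xi_y = excursion(vp)

    drift_u = np.zeros((grid.n_axial, grid.n_transverse))
    drift_v = np.zeros_like(drift_u)
    flagged = np.zeros_like(grid.fluid_mask)
    for k in range(n):
        dudx, dudy, f1 = _masked_gradient(up[k], grid)
        dvdx, dvdy, f2 = _masked_gradient(vp[k], grid)
        drift_u += xi_x[k] * dudx + xi_y[k] * dudy
        drift_v += xi_x[k] * dvdx + xi_y[k] * dvdy
        flagged |= f1 | f2
    drift_u /= n
    drift_v /= n
    fm = grid.fluid_mask
    return SteadyVelocityField(
        grid, np.where(fm, drift_u, 0.0), np.where(fm, drift_v, 0.0),
        "stokes_drift", metadata={"one_sided_cells": flagged},
    )


def lagrangian_mean_asymptotic(field: PeriodicVelocityField) -> SteadyVelocityField:
    """Asymptotic mean Lagrangian velocity: streaming + Stokes drift.

    Strictly valid only for small dimensionless stroke length (eps << 1).
    """
    mean = cycle_average(field)
    drift = stokes_drift_asymptotic(field)
    return SteadyVelocityField(
        field.grid, mean.u + drift.u, mean.v + drift.v, "lagrangian_raw",
        metadata={"method": "asymptotic", **drift.metadata},
    )


# ---------------------------------------------------------------------------
# particle tracking

class _FieldInterpolator:
    """Tri-linear interpolation of (u, v) in (t, x, y).

    Temporal interpolation is periodic-linear between snapshots; spatial
    interpolation is bilinear on cell centres with a periodic ghost column
    in x and mirror-negated ghost rows at the walls so that the interpolated
    velocity vanishes on the wall (the no-slip contract).  Solid cells hold
    zero velocity, so the interpolant tapers to zero at obstacle boundaries.
    """

    def __init__(self, field: PeriodicVelocityField):
        grid = field.grid
        if not grid.axial_periodic:
            raise InputError("particle tracking expects an axially periodic field")
        self.grid = grid
        self.period = field.period
        n = field.n_phases
        t = np.concatenate([field.phase_times, [field.period]])
        vals = np.stack([field.u, field.v], axis=-1)       # (n, nx, ny, 2)
        vals = np.concatenate([vals, vals[:1]], axis=0)    # periodic closure
        # ghost column each side in x (wrap)
        vals = np.concatenate([vals[:, -1:], vals, vals[:, :1]], axis=1)
        x = np.concatenate(
            [[grid.x_centers[0] - grid.dx], grid.x_centers,
             [grid.x_centers[-1] + grid.dx]]
        )
        if field.metadata.get("slip_walls"):
            # unbounded analytic field: linear extrapolation beyond the edge
            vals = np.concatenate(
                [2 * vals[:, :, :1] - vals[:, :, 1:2], vals,
                 2 * vals[:, :, -1:] - vals[:, :, -2:-1]],
                axis=2,
            )
        else:
            # wall-bounded: mirror-negated ghost rows -> zero on the wall
            vals = np.concatenate([-vals[:, :, :1], vals, -vals[:, :, -1:]], axis=2)
        y = np.concatenate(
            [[grid.y_centers[0] - grid.dy], grid.y_centers,
             [grid.y_centers[-1] + grid.dy]]
        )
        self._rgi = RegularGridInterpolator(
            (t, x, y), vals, method="linear", bounds_error=False, fill_value=0.0
        )
        self._y_lim = (y[0], y[-1])

    def __call__(self, x, y, t):
        xw = self.grid.wrap_x(x)
        yc = np.clip(y, *self._y_lim)
        tm = np.mod(t, self.period)
        pts = np.stack(
            [np.broadcast_to(tm, xw.shape), xw, yc], axis=-1
        )
        out = self._rgi(pts)
        return out[..., 0], out[..., 1]


def _integrate(
    interp: _FieldInterpolator,
    x0: np.ndarray,
    y0: np.ndarray,
    t_i: float,
    n_cycles: int,
    substeps_per_cycle: int,
    record: bool = False,
):
    """Vectorised RK4 advection of a particle batch; returns final state.

    Positions are kept unwrapped in x; particles whose position lands in a
    solid cell are frozen with status ``entered_solid``.
    """
    grid = interp.grid
    T = interp.period
    n_steps = n_cycles * substeps_per_cycle
    h = T / substeps_per_cycle
    x = np.asarray(x0, dtype=float).copy()
    y = np.asarray(y0, dtype=float).copy()
    active = np.ones(x.shape, dtype=bool)
    solid = grid.solid_mask
    # trapezoidal accumulation of the cycle-mean position
    xo_acc = 0.5 * x.copy()
    yo_acc = 0.5 * y.copy()
    traj = [np.stack([x, y], axis=-1)] if record else None

    t = t_i
    for step in range(n_steps):
        u1, v1 = interp(x, y, t)
        u2, v2 = interp(x + 0.5 * h * u1, y + 0.5 * h * v1, t + 0.5 * h)
        u3, v3 = interp(x + 0.5 * h * u2, y + 0.5 * h * v2, t + 0.5 * h)
        u4, v4 = interp(x + h * u3, y + h * v3, t + h)
        dx = (h / 6.0) * (u1 + 2 * u2 + 2 * u3 + u4)
        dy = (h / 6.0) * (v1 + 2 * v2 + 2 * v3 + v4)
        x = np.where(active, x + dx, x)
        y = np.where(active, y + dy, y)
        i, j = grid.locate(grid.wrap_x(x), y)
        hit = active & solid[i, j]
        active &= ~hit
        w = 0.5 if step == n_steps - 1 else 1.0
        xo_acc += w * x
        yo_acc += w * y
        t += h
        if record:
            traj.append(np.stack([x, y], axis=-1))

    status = np.where(active, STATUS_OK, STATUS_SOLID)
    x_o = xo_acc / n_steps
    y_o = yo_acc / n_steps
    out = {
        "x": x, "y": y, "x_o": x_o, "y_o": y_o, "status": status,
    }
    if record:
        out["trajectory"] = np.stack(traj, axis=0)
    return out


def advect_particle(
    field: PeriodicVelocityField,
    x_i: tuple[float, float],
    t_i: float = 0.0,
    n_cycles: int = 1,
    substeps_per_cycle: int | None = None,
):
    """Trajectory of one fluid particle advected by the periodic field.

    Integrates dx_p/dt = v(x_p, t) with a classical 4-stage (RK4) scheme;
    the substep never exceeds the snapshot interval.  Returns
    ``(trajectory, status)`` with trajectory of shape ``(n_steps+1, 2)`` in
    unwrapped coordinates.
    """
    i, j = field.grid.locate(field.grid.wrap_x(x_i[0]), x_i[1])
    if field.grid.solid_mask[i, j]:
        raise InputError("seed position lies inside a solid cell")
    sub = substeps_per_cycle or field.n_phases
    interp = _FieldInterpolator(field)
    res = _integrate(
        interp, np.array([x_i[0]]), np.array([x_i[1]]), t_i, n_cycles, sub,
        record=True,
    )
    return res["trajectory"][:, 0, :], str(res["status"][0])


# ---------------------------------------------------------------------------
# trajectory-based mean Lagrangian velocity

@dataclass
class ParticleSet:
    """Seeded fluid particles with cycle displacements and mean positions.

    ``table`` columns: particle id, seeding phase t_i, seed position
    (x_i, y_i), cycle displacement (dx, dy) in unwrapped coordinates,
    cycle-mean position (x_o, y_o) wrapped into the domain, and status.
    """

    grid: StructuredGrid
    period: float
    table: pd.DataFrame

    @property
    def n_ok(self) -> int:
        return int((self.table["status"] == STATUS_OK).sum())

    def ok(self) -> pd.DataFrame:
        return self.table[self.table["status"] == STATUS_OK]

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid: StructuredGrid, period: float):
        return cls(grid, period, pd.read_csv(path))


def lagrangian_mean_from_trajectories(
    field: PeriodicVelocityField,
    seeding: str | np.ndarray = "cell_centers",
    phases: np.ndarray | None = None,
    substeps_per_cycle: int | None = None,
    status_warn_fraction: float = 0.05,
) -> ParticleSet:
    """Trajectory-based mean Lagrangian velocity samples v*_L = delta_x / T.

    Particles are seeded at every fluid-cell centre (default) and advected
    for one cycle from each of 20 equispaced seeding phases; every
    (seed, phase) sample is recorded at its own cycle-mean position x_o.
    Deposition on the grid and phase averaging is done by
    :func:`scatter_to_grid`.
    """
    grid = field.grid
    if isinstance(seeding, str):
        if seeding != "cell_centers":
            raise InputError("seeding must be 'cell_centers' or an (N, 2) array")
        ii, jj = np.nonzero(grid.fluid_mask)
        seeds_x = grid.x_centers[ii]
        seeds_y = grid.y_centers[jj]
    else:
        seeds = np.asarray(seeding, dtype=float)
        seeds_x, seeds_y = seeds[:, 0], seeds[:, 1]
    if phases is None:
        phases = np.arange(20) * field.period / 20.0
    sub = substeps_per_cycle or field.n_phases

    interp = _FieldInterpolator(field)
    frames = []
    for p_idx, t_i in enumerate(np.asarray(phases, dtype=float)):
        res = _integrate(interp, seeds_x, seeds_y, t_i, 1, sub)
        dx = res["x"] - seeds_x
        dy = res["y"] - seeds_y
        frames.append(
            pd.DataFrame(
                {
                    "particle": np.arange(seeds_x.size),
                    "phase_index": p_idx,
                    "t_i": t_i,
                    "x_i": seeds_x,
                    "y_i": seeds_y,
                    "dx": dx,
                    "dy": dy,
                    "x_o": grid.wrap_x(res["x_o"]),
                    "y_o": res["y_o"],
                    "u_star": dx / field.period,
                    "v_star": dy / field.period,
                    "status": res["status"],
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    bad = (table["status"] != STATUS_OK).mean()
    if bad > status_warn_fraction:
        warnings.warn(
            f"{100 * bad:.1f}% of particle samples truncated "
            f"({(table['status'] != STATUS_OK).sum()} of {len(table)}); "
            "they are excluded from the scattered drift set",
            stacklevel=2,
        )
    return ParticleSet(grid, field.period, table)


def scatter_to_grid(
    particles: ParticleSet, grid: StructuredGrid | None = None
) -> SteadyVelocityField:
    """Deposit scattered v*_L samples onto cell centres (role lagrangian_raw).

    Each seeding phase is interpolated separately (simplex-based linear
    interpolation with axial periodic tiling of the sample cloud) and the
    per-phase grids are averaged; cells with no linear-interpolation support
    are filled by nearest-neighbour and flagged in the metadata.
    """
    grid = grid or particles.grid
    ok = particles.ok()
    if len(ok) == 0:
        raise InputError("no valid particle samples to deposit")
    xc, yc = np.meshgrid(grid.x_centers, grid.y_centers, indexing="ij")
    targets = np.stack([xc.ravel(), yc.ravel()], axis=-1)
    L = grid.segment_length

    sums_u = np.zeros(targets.shape[0])
    sums_v = np.zeros(targets.shape[0])
    counts_u = np.zeros(targets.shape[0])
    filled = np.zeros(targets.shape[0], dtype=bool)
    for _, sub in ok.groupby("phase_index"):
        pts = np.stack([sub["x_o"].to_numpy(), sub["y_o"].to_numpy()], axis=-1)
        vals = np.stack([sub["u_star"].to_numpy(), sub["v_star"].to_numpy()], axis=-1)
        if grid.axial_periodic:
            pts = np.concatenate(
                [pts, pts + np.array([L, 0.0]), pts - np.array([L, 0.0])]
            )
            vals = np.concatenate([vals, vals, vals])
        lin = griddata(pts, vals, targets, method="linear")
        nan = np.isnan(lin[:, 0])
        if np.any(nan):
            near = griddata(pts, vals, targets[nan], method="nearest")
            lin[nan] = near
            filled |= nan
        sums_u += lin[:, 0]
        sums_v += lin[:, 1]
        counts_u += 1.0
    u = (sums_u / counts_u).reshape(xc.shape)
    v = (sums_v / counts_u).reshape(xc.shape)
    fm = grid.fluid_mask
    u = np.where(fm, u, 0.0)
    v = np.where(fm, v, 0.0)
    return SteadyVelocityField(
        grid, u, v, "lagrangian_raw",
        metadata={
            "method": "trajectories",
            "n_phases_averaged": int(ok["phase_index"].nunique()),
            "nearest_filled_cells": filled.reshape(xc.shape) & fm,
        },
    )


def lagrangian_mean_raw(
    field: PeriodicVelocityField, **kwargs
) -> tuple[ParticleSet, SteadyVelocityField]:
    """Convenience: particle tracking + deposition in one call."""
    particles = lagrangian_mean_from_trajectories(field, **kwargs)
    return particles, scatter_to_grid(particles)
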