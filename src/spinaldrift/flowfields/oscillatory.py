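"""2-D oscillatory incompressible Navier-Stokes channel solver.

Integrates

    div v = 0,   dv/dt + v . grad v = -(1/rho) grad p + nu lap v

in a plane channel that is periodic in the axial direction, with no-slip on
the channel walls and on interior stair-step obstacle masks.  A spatially
uniform axial body force (the surrogate for the section-to-section pressure
difference driving the flow) is adjusted every step by a
proportional-integral(-derivative) controller so that the instantaneous
cross-sectional flow rate tracks a prescribed waveform, and the integration
is continued until the solution is time-periodic.

Discretisation: MAC staggered grid; fractional-step (projection) method;
explicit Adams-Bashforth-2 advection in conservative form; Crank-Nicolson
(semi-implicit) viscous terms; pressure Poisson solve with a compact 5-point
Laplacian.  All sparse operators are assembled and LU-factorised once.  The
scheme is second order in space.

The controller's proportional gain acts on the flow-rate error normalised by
the precomputed discrete flow-rate response of a unit body force, so a gain
of 1 cancels the instantaneous error (dead-beat); the applied forcing history
is simultaneously learned into a per-phase feedforward table, which plays the
role of the integral term across cycles.  Convergence is declared from the
cycle-to-cycle periodicity residual max|v(.,t) - v(.,t+T)| / max|v|.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from ..errors import ConvergenceError, InputError, StabilityError
from ..fields import PeriodicVelocityField
from ..grid import SPAN_CM, StructuredGrid
from ..waveforms import FluidParams, FlowRateWaveform

DEFAULT_TOL_PERIODIC = 1e-4


@dataclass(frozen=True)
class ControllerGains:
    """PID gains acting on the normalised flow-rate error.

    ``proportional = 1`` cancels the instantaneous error exactly (dead-beat);
    the derivative gain defaults to 0.  ``learning`` controls how much of the
    applied forcing is written back into the per-phase feedforward table
    (integral action across cycles).
    """

    proportional: float = 1.0
    integral: float = 0.0
    derivative: float = 0.0
    learning: float = 1.0


@dataclass
class ControllerState:
    """Controller trace returned alongside the converged velocity field."""

    gains: ControllerGains
    forcing: np.ndarray               # converged body force per phase, cm/s^2
    forcing_times: np.ndarray         # phase times, s
    pressure_difference: np.ndarray   # rho * a * L_seg surrogate, Pa
    cycle_error_norms: list = dataclass_field(default_factory=list)
    periodicity_residuals: list = dataclass_field(default_factory=list)
    n_cycles: int = 0
    converged: bool = False

    @property
    def forcing_amplitude(self) -> float:
        return float(np.max(self.forcing) - np.min(self.forcing)) / 2.0

    @property
    def pressure_amplitude(self) -> float:
        return float(
            np.max(self.pressure_difference) - np.min(self.pressure_difference)
        ) / 2.0


class _ChannelOperators:
    """Sparse operators and LU factors for a given grid / fluid / dt."""

    def __init__(self, grid: StructuredGrid, nu: float, dt: float):
        self.grid, self.nu, self.dt = grid, nu, dt
        nx, ny = grid.n_axial, grid.n_transverse
        fm = grid.fluid_mask
        self.ufl = np.roll(fm, 1, axis=0) & fm                     # (nx, ny)
        vfl = np.zeros((nx, ny + 1), dtype=bool)
        vfl[:, 1:-1] = fm[:, :-1] & fm[:, 1:]
        self.vfl = vfl
        self.A_u = splu(self._helmholtz_matrix("u"))
        self.A_v = splu(self._helmholtz_matrix("v"))
        self.Lp = self._pressure_matrix()
        self.P = splu(self.Lp.tocsc())
        self._response()

    # -- assembly --------------------------------------------------------

    def _helmholtz_matrix(self, which: str):
        """I - (nu dt / 2) * Lap on u- or v-faces, Dirichlet rows identity."""
        grid, nu, dt = self.grid, self.nu, self.dt
        nx, ny = grid.n_axial, grid.n_transverse
        dx2, dy2 = grid.dx**2, grid.dy**2
        if which == "u":
            fluid = self.ufl
            shape = (nx, ny)
        else:
            fluid = self.vfl
            shape = (nx, ny + 1)
        n = shape[0] * shape[1]

        def idx(i, j):
            return np.mod(i, shape[0]) * shape[1] + j

        rows, cols, vals = [], [], []
        I, J = np.nonzero(fluid)
        diag = np.zeros(len(I))
        for axis, (di, dj) in enumerate([(-1, 0), (1, 0), (0, -1), (0, 1)]):
            c = 1.0 / dx2 if axis < 2 else 1.0 / dy2
            ni = I + di
            nj = J + dj
            # periodic in x for both face families
            in_range = (nj >= 0) & (nj < shape[1])
            nbr_fluid = np.zeros(len(I), dtype=bool)
            ok = in_range
            nbr_fluid[ok] = fluid[np.mod(ni[ok], shape[0]), nj[ok]]
            diag -= c
            # mirror (wall at half spacing) vs Dirichlet-at-node cases:
            # u-faces: y-neighbours mirror, x-neighbours Dirichlet;
            # v-faces: x-neighbours mirror, y-neighbours Dirichlet.
            mirror_axis = axis >= 2 if which == "u" else axis < 2
            blocked = ~nbr_fluid
            if mirror_axis:
                diag[blocked] -= c
            keep = nbr_fluid
            rows.append(idx(I[keep], J[keep]))
            cols.append(idx(ni[keep], nj[keep]))
            vals.append(np.full(keep.sum(), c))
        rows.append(idx(I, J))
        cols.append(idx(I, J))
        vals.append(diag)
        L = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        A = sp.identity(n, format="csr") - 0.5 * nu * dt * L
        # Dirichlet (solid/wall) faces: identity rows
        solid_flat = np.flatnonzero(~fluid.ravel())
        A = A.tolil()
        A[solid_flat, :] = 0.0
        A[solid_flat, solid_flat] = 1.0
        self._lap = getattr(self, "_lap", {})
        self._lap[which] = L
        return A.tocsc()

    def _pressure_matrix(self):
        grid = self.grid
        nx, ny = grid.n_axial, grid.n_transverse
        fm = grid.fluid_mask
        dx2, dy2 = grid.dx**2, grid.dy**2
        n = nx * ny

        def idx(i, j):
            return np.mod(i, nx) * ny + j

        rows, cols, vals = [], [], []
        I, J = np.nonzero(fm)
        diag = np.zeros(len(I))
        for axis, (di, dj) in enumerate([(-1, 0), (1, 0), (0, -1), (0, 1)]):
            c = 1.0 / dx2 if axis < 2 else 1.0 / dy2
            ni, nj = I + di, J + dj
            in_range = (nj >= 0) & (nj < ny)
            nbr_fluid = np.zeros(len(I), dtype=bool)
            nbr_fluid[in_range] = fm[np.mod(ni[in_range], nx), nj[in_range]]
            # Neumann: only fluid-fluid links contribute
            diag -= c * nbr_fluid
            keep = nbr_fluid
            rows.append(idx(I[keep], J[keep]))
            cols.append(idx(ni[keep], nj[keep]))
            vals.append(np.full(keep.sum(), c))
        rows.append(idx(I, J))
        cols.append(idx(I, J))
        vals.append(diag)
        L = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tolil()
        solid_flat = np.flatnonzero(~fm.ravel())
        L[solid_flat, :] = 0.0
        L[solid_flat, solid_flat] = 1.0
        # pin the gauge at the first fluid cell
        self.pin = int(np.flatnonzero(fm.ravel())[0])
        L[self.pin, :] = 0.0
        L[self.pin, self.pin] = 1.0
        return L

    def laplacian(self, which: str, f: np.ndarray) -> np.ndarray:
        return (self._lap[which] @ f.ravel()).reshape(f.shape)

    # -- projection ------------------------------------------------------

    def project(self, uf: np.ndarray, vf: np.ndarray):
        grid = self.grid
        div = (np.roll(uf, -1, axis=0) - uf) / grid.dx + (
            vf[:, 1:] - vf[:, :-1]
        ) / grid.dy
        rhs = np.where(grid.fluid_mask, div, 0.0)
        nf = grid.fluid_mask.sum()
        rhs -= grid.fluid_mask * (rhs.sum() / nf)
        rhs_flat = rhs.ravel().copy()
        rhs_flat[self.pin] = 0.0
        phi = self.P.solve(rhs_flat).reshape(div.shape)
        uf = uf - np.where(self.ufl, (phi - np.roll(phi, 1, axis=0)) / grid.dx, 0.0)
        gy = np.zeros_like(vf)
        gy[:, 1:-1] = (phi[:, 1:] - phi[:, :-1]) / grid.dy
        vf = vf - np.where(self.vfl, gy, 0.0)
        return uf, vf, phi

    def _response(self):
        """Flow-rate response of a unit uniform body force over one step."""
        rhs = np.where(self.ufl, self.dt, 0.0)
        r_u = self.A_u.solve(rhs.ravel()).reshape(rhs.shape)
        r_v = np.zeros((self.grid.n_axial, self.grid.n_transverse + 1))
        r_u, r_v, _ = self.project(r_u, r_v)
        self.r_u, self.r_v = r_u, r_v
        self.q_gain = float(r_u[0].sum() * self.grid.dy * SPAN_CM)

    def flow_rate(self, uf: np.ndarray) -> float:
        return float(uf[0].sum() * self.grid.dy * SPAN_CM)

    # -- advection -------------------------------------------------------

    def advection(self, uf: np.ndarray, vf: np.ndarray):
        grid = self.grid
        dx, dy = grid.dx, grid.dy
        nx, ny = grid.n_axial, grid.n_transverse
        uc = 0.5 * (uf + np.roll(uf, -1, axis=0))          # u at cell centres
        # corner (x-node, y-node) values, shape (nx, ny+1)
        cu = np.zeros((nx, ny + 1))
        cu[:, 1:-1] = 0.5 * (uf[:, :-1] + uf[:, 1:])       # zero on walls
        cv = 0.5 * (np.roll(vf, 1, axis=0) + vf)
        flux_uv = cu * cv
        n_u = (uc**2 - np.roll(uc, 1, axis=0) ** 2) / dx + (
            flux_uv[:, 1:] - flux_uv[:, :-1]
        ) / dy
        vc = 0.5 * (vf[:, :-1] + vf[:, 1:])                # v at cell centres
        n_v = np.zeros_like(vf)
        n_v[:, 1:-1] = (
            np.roll(flux_uv, -1, axis=0)[:, 1:-1] - flux_uv[:, 1:-1]
        ) / dx + (vc[:, 1:] - vc[:, :-1]) / dy
        return np.where(self.ufl, n_u, 0.0), np.where(self.vfl, n_v, 0.0)


def solve_oscillatory_channel(
    grid: StructuredGrid,
    waveform: FlowRateWaveform,
    fluid: FluidParams,
    gains: ControllerGains | None = None,
    n_adjust_cycles: int = 100,
    dt: float | None = None,
    n_store: int = 100,
    tol_periodic: float = DEFAULT_TOL_PERIODIC,
    cfl_limit: float = 0.9,
    min_cycles: int = 3,
) -> tuple[PeriodicVelocityField, ControllerState]:
    """Solve for the permanent time-periodic flow matching a flow-rate target.

    Returns the final cycle as a :class:`PeriodicVelocityField` (with exact
    staggered face data) once the periodicity residual drops below
    ``tol_periodic``, together with the controller trace.  Raises
    :class:`ConvergenceError` (carrying the residual history) if the limit
    cycle is not reached within ``n_adjust_cycles`` and
    :class:`StabilityError` on advective CFL violation.
    """
    if not grid.axial_periodic:
        raise InputError("the oscillatory solver requires an axially periodic grid")
    gains = gains or ControllerGains()
    T = waveform.period
    if dt is None:
        dt = T / 200.0
    spc = int(round(T / dt))
    if abs(spc * dt - T) > 1e-12 * T:
        raise InputError("dt must divide the period")
    n_store = min(n_store, spc)
    if spc % n_store:
        raise InputError("steps per cycle must be a multiple of n_store")
    stride = spc // n_store

    nu = fluid.nu_cm2s
    ops = _ChannelOperators(grid, nu, dt)
    nx, ny = grid.n_axial, grid.n_transverse

    uf = np.zeros((nx, ny))
    vf = np.zeros((nx, ny + 1))
    n_u_old, n_v_old = ops.advection(uf, vf)
    a_ff = np.zeros(spc)
    q_targets = waveform((np.arange(spc) + 1) * dt)
    q_scale = max(np.max(np.abs(waveform.flow_rate)), 1e-300)

    snaps_u = np.zeros((n_store, nx, ny))
    snaps_v = np.zeros((n_store, nx, ny + 1))
    prev_u = prev_v = None
    err_int = 0.0
    e_prev = 0.0
    error_norms: list[float] = []
    residuals: list[float] = []
    converged = False
    n_cycles = 0

    for cycle in range(n_adjust_cycles):
        errs = np.zeros(spc)
        for k in range(spc):
            if k % stride == 0:
                snaps_u[k // stride] = uf
                snaps_v[k // stride] = vf
            n_u, n_v = ops.advection(uf, vf)
            adv_u = 1.5 * n_u - 0.5 * n_u_old
            adv_v = 1.5 * n_v - 0.5 * n_v_old
            n_u_old, n_v_old = n_u, n_v
            rhs_u = uf + dt * (
                -adv_u + 0.5 * nu * ops.laplacian("u", uf) + a_ff[k]
            )
            rhs_v = vf + dt * (-adv_v + 0.5 * nu * ops.laplacian("v", vf))
            rhs_u = np.where(ops.ufl, rhs_u, 0.0)
            rhs_v = np.where(ops.vfl, rhs_v, 0.0)
            uf = ops.A_u.solve(rhs_u.ravel()).reshape(rhs_u.shape)
            vf = ops.A_v.solve(rhs_v.ravel()).reshape(rhs_v.shape)
            uf, vf, _ = ops.project(uf, vf)
            # controller: correct the flow rate toward the target
            e = q_targets[k] - ops.flow_rate(uf)
            errs[k] = e
            err_int += e * dt
            da = (
                gains.proportional * e
                + gains.integral * err_int
                + gains.derivative * (e - e_prev)
            ) / ops.q_gain
            e_prev = e
            uf = uf + da * ops.r_u
            vf = vf + da * ops.r_v
            a_ff[k] += gains.learning * da
        n_cycles = cycle + 1
        error_norms.append(float(np.sqrt(np.mean(errs**2)) / q_scale))

        cfl = dt * (np.max(np.abs(uf)) / grid.dx + np.max(np.abs(vf)) / grid.dy)
        if cfl > cfl_limit:
            raise StabilityError(
                f"advective CFL {cfl:.2f} exceeds limit {cfl_limit} at dt={dt}"
            )
        if prev_u is not None:
            scale = max(np.max(np.abs(snaps_u)), np.max(np.abs(snaps_v)))
            if scale < 1e-14:
                res = 0.0
            else:
                res = max(
                    np.max(np.abs(snaps_u - prev_u)), np.max(np.abs(snaps_v - prev_v))
                ) / scale
            residuals.append(float(res))
            if res <= tol_periodic and n_cycles >= min_cycles:
                converged = True
                break
        prev_u = snaps_u.copy()
        prev_v = snaps_v.copy()

    state = ControllerState(
        gains=gains,
        forcing=a_ff.copy(),
        forcing_times=np.arange(spc) * dt,
        # a [cm/s^2] * L [cm] * rho [kg/m^3] -> Pa via 1e-4 m^2/cm^2
        pressure_difference=a_ff * grid.segment_length * fluid.density * 1e-4,
        cycle_error_norms=error_norms,
        periodicity_residuals=residuals,
        n_cycles=n_cycles,
        converged=converged,
    )
    if not converged:
        raise ConvergenceError(
            f"no periodic solution within {n_adjust_cycles} cycles "
            f"(last residual {residuals[-1] if residuals else np.nan:.3e})",
            history=residuals,
        )

    # package the final cycle: duplicate the periodic u-face plane
    u_face = np.concatenate([snaps_u, snaps_u[:, :1]], axis=1)
    u_c = 0.5 * (u_face[:, :-1] + u_face[:, 1:])
    v_c = 0.5 * (snaps_v[:, :, :-1] + snaps_v[:, :, 1:])
    solid = grid.solid_mask
    u_c[:, solid] = 0.0
    v_c[:, solid] = 0.0
    field = PeriodicVelocityField(
        grid, T, u_c, v_c, u_face, snaps_v.copy(),
        metadata={
            "solver": "projection_mac_cn_ab2",
            "dt": dt,
            "n_cycles": n_cycles,
            "periodicity_residual": residuals[-1] if residuals else 0.0,
        },
    )
    return field, state
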