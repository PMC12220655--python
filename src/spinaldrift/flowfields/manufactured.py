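"""Manufactured periodic flows with closed-form mean Lagrangian drift.

The fields are built from the stream function

    psi(x, y, t) = U * (y - y_mid) * cos(k x - w t)        (traveling)
    psi(x, y, t) = U * (y - y_mid) * cos(k x) * cos(w t)   (standing)

so that u = d(psi)/dy, v = -d(psi)/dx are exactly divergence-free.  The
traveling wave has axial velocity u = U cos(kx - wt) and a classical Stokes
drift U^2 k / (2 w) directed along the wave propagation, with zero
cycle-averaged Eulerian velocity — the canonical example of a purely
oscillatory flow whose fluid particles nevertheless drift.  The standing wave
has zero drift.  The closed-form cycle mean and drift are attached as
metadata so downstream operators can be tested against them.

Face velocities are obtained by differencing the stream function at grid
nodes, which makes the *discrete* face divergence vanish to round-off.
"""

from __future__ import annotations

import numpy as np

from ..errors import InputError, ResolutionError
from ..fields import PeriodicVelocityField
from ..grid import StructuredGrid

MIN_CELLS_PER_WAVELENGTH = 16


def make_manufactured_wave_flow(
    grid: StructuredGrid,
    amplitude: float,
    wavenumber: float,
    period: float,
    kind: str = "traveling",
    n_phases: int = 100,
) -> PeriodicVelocityField:
    """Analytic wave flow on an obstacle-free grid.

    Parameters
    ----------
    amplitude : peak axial velocity U, cm/s.
    wavenumber : axial wavenumber k, 1/cm.
    period : oscillation period T, s.
    kind : ``"traveling"`` or ``"standing"``.

    The dimensionless stroke length of the wave is ``eps = U k / w`` (particle
    excursion U/w over the wave scale 1/k); the small-stroke asymptotics for
    the drift are accurate to O(eps).
    """
    if kind not in ("traveling", "standing"):
        raise InputError(f"kind must be 'traveling' or 'standing', got {kind!r}")
    if np.any(grid.solid_mask):
        raise InputError("manufactured wave flows require an obstacle-free grid")
    if wavenumber <= 0 or period <= 0:
        raise InputError("wavenumber and period must be positive")
    wavelength = 2 * np.pi / wavenumber
    if wavelength / grid.dx < MIN_CELLS_PER_WAVELENGTH:
        raise ResolutionError(
            f"wavelength {wavelength:.3g} cm resolved by only "
            f"{wavelength / grid.dx:.1f} cells (< {MIN_CELLS_PER_WAVELENGTH})"
        )

    U, k = float(amplitude), float(wavenumber)
    omega = 2 * np.pi / period
    y_mid = grid.origin[1] + grid.height / 2.0

    x_c = grid.x_centers
    y_c = grid.y_centers
    x_n = grid.origin[0] + np.arange(grid.n_axial + 1) * grid.dx   # face/node x
    y_n = grid.origin[1] + np.arange(grid.n_transverse + 1) * grid.dy

    times = np.arange(n_phases) * period / n_phases
    nx, ny = grid.n_axial, grid.n_transverse
    u = np.empty((n_phases, nx, ny))
    v = np.empty((n_phases, nx, ny))
    uf = np.empty((n_phases, nx + 1, ny))
    vf = np.empty((n_phases, nx, ny + 1))

    def phase_fn(xv, t):
        if kind == "traveling":
            return np.cos(k * xv - omega * t)
        return np.cos(k * xv) * np.cos(omega * t)

    def psi(xv, yv, t):
        return U * (yv - y_mid) * phase_fn(xv, t)

    for m, t in enumerate(times):
        # centres, sampled from the analytic derivatives
        u[m] = np.broadcast_to(phase_fn(x_c, t)[:, None] * U, (nx, ny))
        if kind == "traveling":
            dpdx = U * k * np.sin(k * x_c - omega * t)
        else:
            dpdx = U * k * np.sin(k * x_c) * np.cos(omega * t)
        v[m] = dpdx[:, None] * (y_c - y_mid)[None, :]
        # faces, from nodal stream-function differences (exactly solenoidal)
        psi_u = psi(x_n[:, None], y_n[None, :], t)           # (nx+1, ny+1)
        uf[m] = (psi_u[:, 1:] - psi_u[:, :-1]) / grid.dy
        psi_v = psi(x_n[:, None], y_n[None, :], t)
        vf[m] = -(psi_v[1:, :] - psi_v[:-1, :]) / grid.dx

    drift_u = np.zeros((nx, ny))
    if kind == "traveling":
        drift_u += U**2 * k / (2 * omega)
    meta = {
        "kind": kind,
        "slip_walls": True,
        "amplitude": U,
        "wavenumber": k,
        "omega": omega,
        "epsilon": U * k / omega,
        "closed_form_mean_u": np.zeros((nx, ny)),
        "closed_form_mean_v": np.zeros((nx, ny)),
        "closed_form_drift_u": drift_u,
        "closed_form_drift_v": np.zeros((nx, ny)),
    }
    return PeriodicVelocityField(grid, period, u, v, uf, vf, meta)
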