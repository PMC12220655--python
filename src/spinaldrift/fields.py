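"""Velocity-field containers.

Two containers cover everything the pipeline exchanges:

* :class:`PeriodicVelocityField` — one cycle of a T-periodic incompressible
  velocity field, stored as equally spaced phase snapshots;
* :class:`SteadyVelocityField` — a time-independent field (cycle-averaged
  Eulerian velocity, Stokes drift, raw or solenoidal mean Lagrangian
  velocity, or a potential gradient), tagged with its role.

Velocities are cell-centred (cm/s) for user-facing work.  Fields produced by
the incompressible solver, the stream-function generators and the Helmholtz
projection additionally carry a staggered (face) representation on which the
discrete divergence vanishes identically; conservative transport and the
projection itself operate on faces when they are available.

Face layout: ``u_face`` has shape ``(n_phases, nx + 1, ny)`` with
``u_face[..., i, j]`` the axial velocity on the face at ``x = x0 + i*dx``
(for axially periodic grids the first and last planes are duplicates);
``v_face`` has shape ``(n_phases, nx, ny + 1)`` with the ``j = 0`` and
``j = ny`` planes lying on the channel walls.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .errors import InputError
from .grid import StructuredGrid

ROLES = (
    "eulerian_mean",
    "stokes_drift",
    "lagrangian_raw",
    "lagrangian_solenoidal",
    "potential_gradient",
)


# ---------------------------------------------------------------------------
# face/center conversions

def x_face_fluid(grid: StructuredGrid) -> np.ndarray:
    """Fluid mask on x-faces, shape (nx+1, ny)."""
    fm = grid.fluid_mask
    out = np.zeros((grid.n_axial + 1, grid.n_transverse), dtype=bool)
    out[1:-1] = fm[:-1] & fm[1:]
    if grid.axial_periodic:
        out[0] = out[-1] = fm[-1] & fm[0]
    else:
        out[0] = fm[0]
        out[-1] = fm[-1]
    return out


def y_face_fluid(grid: StructuredGrid) -> np.ndarray:
    """Fluid mask on y-faces, shape (nx, ny+1); wall faces are solid."""
    fm = grid.fluid_mask
    out = np.zeros((grid.n_axial, grid.n_transverse + 1), dtype=bool)
    out[:, 1:-1] = fm[:, :-1] & fm[:, 1:]
    return out


def faces_from_centers(u, v, grid: StructuredGrid):
    """Average cell-centred components to faces, zeroing solid/wall faces.

    Zeroing the wall-normal faces realises the impermeability contract
    v . n = 0 on solid boundaries.  On obstacle-free interior cells the
    resulting face divergence equals the centred-difference divergence of
    the centre field (an algebraic identity of the averaging).
    """
    nx, ny = grid.n_axial, grid.n_transverse
    uf = np.zeros((nx + 1, ny))
    uf[1:-1] = 0.5 * (u[:-1] + u[1:])
    if grid.axial_periodic:
        uf[0] = uf[-1] = 0.5 * (u[-1] + u[0])
    else:
        uf[0] = u[0]
        uf[-1] = u[-1]
    vf = np.zeros((nx, ny + 1))
    vf[:, 1:-1] = 0.5 * (v[:, :-1] + v[:, 1:])
    uf[~x_face_fluid(grid)] = 0.0
    vf[~y_face_fluid(grid)] = 0.0
    return uf, vf


def centers_from_faces(uf, vf, grid: StructuredGrid):
    """Average face components back to cell centres (zero in solid cells)."""
    u = 0.5 * (uf[:-1] + uf[1:])
    v = 0.5 * (vf[:, :-1] + vf[:, 1:])
    solid = grid.solid_mask
    u = np.where(solid, 0.0, u)
    v = np.where(solid, 0.0, v)
    return u, v


def face_divergence(uf, vf, grid: StructuredGrid) -> np.ndarray:
    """Per-cell divergence of a face field (zero in solid cells), 1/s."""
    div = (uf[1:] - uf[:-1]) / grid.dx + (vf[:, 1:] - vf[:, :-1]) / grid.dy
    return np.where(grid.solid_mask, 0.0, div)


def default_tol_div(grid: StructuredGrid, u_ref: float) -> float:
    """Divergence tolerance 1e-10 * U_ref / dx (with a small absolute floor)."""
    return 1e-10 * max(abs(u_ref), 1e-8) / min(grid.dx, grid.dy)


# ---------------------------------------------------------------------------
# containers

@dataclass
class SteadyVelocityField:
    """A time-independent velocity field on a grid, tagged with its role."""

    grid: StructuredGrid
    u: np.ndarray
    v: np.ndarray
    role: str
    u_face: np.ndarray | None = None
    v_face: np.ndarray | None = None
    metadata: dict = dataclass_field(default_factory=dict)

    def __post_init__(self):
        if self.role not in ROLES:
            raise InputError(f"unknown role {self.role!r}; expected one of {ROLES}")
        shape = (self.grid.n_axial, self.grid.n_transverse)
        if self.u.shape != shape or self.v.shape != shape:
            raise InputError("velocity component shape does not match grid")

    @property
    def has_faces(self) -> bool:
        return self.u_face is not None and self.v_face is not None

    def faces(self):
        """Face representation (stored if available, else averaged)."""
        if self.has_faces:
            return self.u_face, self.v_face
        return faces_from_centers(self.u, self.v, self.grid)

    def divergence(self) -> np.ndarray:
        return face_divergence(*self.faces(), self.grid)

    def max_speed(self) -> float:
        return float(np.max(np.hypot(self.u, self.v)))

    def tile(self, n_segments: int | None = None) -> "SteadyVelocityField":
        """Replicate a field on a periodic segment onto the tiled open grid."""
        grid = self.grid.tile(n_segments)
        n = grid.n_axial // self.grid.n_axial
        uf = vf = None
        if self.has_faces:
            uf = np.concatenate([self.u_face[:-1]] * n + [self.u_face[-1:]], axis=0)
            vf = np.tile(self.v_face, (n, 1))
        return SteadyVelocityField(
            grid, np.tile(self.u, (n, 1)), np.tile(self.v, (n, 1)),
            self.role, uf, vf, dict(self.metadata),
        )


@dataclass
class PeriodicVelocityField:
    """One cycle of a T-periodic velocity field as equally spaced snapshots.

    ``u``/``v`` have shape ``(n_phases, nx, ny)``; snapshot k holds the field
    at phase time ``t_k = k*T/n_phases``, and the index wraps modulo
    ``n_phases`` (the field is periodic by construction).
    """

    grid: StructuredGrid
    period: float
    u: np.ndarray
    v: np.ndarray
    u_face: np.ndarray | None = None
    v_face: np.ndarray | None = None
    metadata: dict = dataclass_field(default_factory=dict)

    def __post_init__(self):
        if self.period <= 0:
            raise InputError("period must be positive")
        if self.u.ndim != 3 or self.u.shape != self.v.shape:
            raise InputError("snapshots must be (n_phases, nx, ny) arrays")
        if self.u.shape[1:] != (self.grid.n_axial, self.grid.n_transverse):
            raise InputError("snapshot shape does not match grid")
        if self.n_phases < 1:
            raise InputError("need at least one phase snapshot")

    @property
    def n_phases(self) -> int:
        return self.u.shape[0]

    @property
    def phase_times(self) -> np.ndarray:
        return np.arange(self.n_phases) * self.period / self.n_phases

    @property
    def has_faces(self) -> bool:
        return self.u_face is not None and self.v_face is not None

    def snapshot_faces(self, k: int):
        k = k % self.n_phases
        if self.has_faces:
            return self.u_face[k], self.v_face[k]
        return faces_from_centers(self.u[k], self.v[k], self.grid)

    def max_speed(self) -> float:
        return float(np.max(np.hypot(self.u, self.v)))

    def max_divergence(self) -> float:
        """Max |discrete divergence| over fluid cells and phases, 1/s."""
        worst = 0.0
        for k in range(self.n_phases):
            div = face_divergence(*self.snapshot_faces(k), self.grid)
            worst = max(worst, float(np.max(np.abs(div))))
        return worst

    def validate_divergence(self, tol: float | None = None) -> float:
        tol = default_tol_div(self.grid, self.max_speed()) if tol is None else tol
        worst = self.max_divergence()
        if worst > tol:
            raise InputError(
                f"field is not divergence-free: max |div| = {worst:.3e} > {tol:.3e}"
            )
        return worst

    def tile(self, n_segments: int | None = None) -> "PeriodicVelocityField":
        """Replicate the periodic-segment field onto the tiled open grid."""
        grid = self.grid.tile(n_segments)
        n = grid.n_axial // self.grid.n_axial
        uf = vf = None
        if self.has_faces:
            uf = np.concatenate(
                [self.u_face[:, :-1]] * n + [self.u_face[:, -1:]], axis=1
            )
            vf = np.tile(self.v_face, (1, n, 1))
        return PeriodicVelocityField(
            grid, self.period,
            np.tile(self.u, (1, n, 1)), np.tile(self.v, (1, n, 1)),
            uf, vf, dict(self.metadata),
        )
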