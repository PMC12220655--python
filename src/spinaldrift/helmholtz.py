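"""Helmholtz decomposition of the trajectory-based mean Lagrangian velocity.

At finite stroke length the trajectory-based mean Lagrangian velocity v*_L
is generally not divergence-free; used directly in the reduced transport
equation its divergence would act as a non-physical distribution of sinks
and sources.  The remedy is the decomposition

    v*_L = v_L + grad(Phi),     lap(Phi) = div(v*_L),     div(v_L) = 0,

with Phi fixed by a zero-mean gauge.  Boundary conditions (the package's
choice): homogeneous-flux walls realised by prescribing
d(Phi)/dn = v*_L . n on solid boundaries — equivalently, the wall-normal
component of the corrected field vanishes, restoring impermeability — and
periodicity in the axial direction.

Discretely the projection operates on a staggered (face) representation:
cell-centred components are averaged to faces (solid and wall normal faces
zeroed), the compact 5-point Poisson problem is solved for Phi at cell
centres, the face field is corrected by the face-normal gradient of Phi and
averaged back to centres.  Because divergence, gradient and Laplacian are
built from the same face stencils the discrete decomposition is orthogonal:
projection is exactly idempotent (the face data ride along on the returned
field) and ||v_L|| <= ||v*_L|| in the discrete L2 norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import ConservationError, ConvergenceError, InputError
from .fields import (
    SteadyVelocityField,
    centers_from_faces,
    default_tol_div,
    face_divergence,
    faces_from_centers,
    x_face_fluid,
    y_face_fluid,
)
from .grid import StructuredGrid

TOL_POISSON = 1e-10


@dataclass
class PotentialField:
    """Scalar potential Phi (cm^2/s) at cell centres, zero-mean gauge."""

    grid: StructuredGrid
    phi: np.ndarray
    metadata: dict = dataclass_field(default_factory=dict)

    def gradient(self) -> SteadyVelocityField:
        """grad(Phi) as a cell-centred field (role potential_gradient)."""
        gx_f, gy_f = _face_gradient(self.phi, self.grid)
        u, v = centers_from_faces(gx_f, gy_f, self.grid)
        return SteadyVelocityField(self.grid, u, v, "potential_gradient", gx_f, gy_f)


def divergence(field: SteadyVelocityField) -> np.ndarray:
    """Discrete divergence of a steady field in fluid cells (1/s).

    Computed as the face divergence of the field's staggered representation
    (stored if the field carries one, otherwise obtained by averaging the
    centre values to faces with impermeable solid/wall faces).  On interior
    obstacle-free cells this equals the centred-difference divergence of the
    centre components; next to walls it is the physically consistent
    one-sided form.  Zero in solid cells.
    """
    return face_divergence(*field.faces(), field.grid)


def _neumann_laplacian(grid: StructuredGrid):
    """Compact 5-point Laplacian: periodic in x, zero-flux at walls/solids.

    Solid cells get identity rows; the constant nullspace is removed by
    pinning the first fluid cell (callers project the source mean).
    """
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
        if not grid.axial_periodic and axis < 2:
            in_range = (ni >= 0) & (ni < nx)
        else:
            in_range = np.ones(len(I), dtype=bool)
        in_range &= (nj >= 0) & (nj < ny)
        nbr = np.zeros(len(I), dtype=bool)
        nbr[in_range] = fm[np.mod(ni[in_range], nx), nj[in_range]]
        diag -= c * nbr
        rows.append(idx(I[nbr], J[nbr]))
        cols.append(idx(ni[nbr], nj[nbr]))
        vals.append(np.full(int(nbr.sum()), c))
    rows.append(idx(I, J))
    cols.append(idx(I, J))
    vals.append(diag)
    L = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    pin = int(np.flatnonzero(fm.ravel())[0])
    Lp = L.tolil()
    solid_flat = np.flatnonzero(~fm.ravel())
    Lp[solid_flat, :] = 0.0
    Lp[solid_flat, solid_flat] = 1.0
    Lp[pin, :] = 0.0
    Lp[pin, pin] = 1.0
    return L, Lp.tocsc(), pin


def solve_poisson(
    source: np.ndarray,
    grid: StructuredGrid,
    boundary_spec: str = "neumann_periodic",
    tol: float = TOL_POISSON,
    incompatibility_tol: float = 0.2,
) -> PotentialField:
    """Solve lap(Phi) = source with zero-flux walls and periodic x.

    The pure-Neumann problem requires a zero-mean source; the fluid-cell
    mean is projected out (and recorded), but a relative imbalance beyond
    ``incompatibility_tol`` is treated as a conservation error.  The
    solution carries a zero-mean gauge; the direct sparse solve is verified
    against ``tol`` (relative residual).
    """
    if boundary_spec != "neumann_periodic":
        raise InputError(f"unsupported boundary_spec {boundary_spec!r}")
    fm = grid.fluid_mask
    s = np.where(fm, np.asarray(source, dtype=float), 0.0)
    scale = float(np.abs(s).sum())
    imbalance = float(abs(s.sum()))
    if scale > 0 and imbalance / scale > incompatibility_tol:
        raise ConservationError(
            f"Poisson source imbalance {imbalance / scale:.2e} exceeds "
            f"{incompatibility_tol}: the flux budget is not conserved"
        )
    nf = int(fm.sum())
    s = s - fm * (s.sum() / nf)

    L, Lp, pin = _neumann_laplacian(grid)
    rhs = s.ravel().copy()
    rhs[pin] = 0.0
    phi = splu(Lp).solve(rhs).reshape(s.shape)
    phi = np.where(fm, phi, 0.0)
    phi -= phi[fm].mean()
    resid = (L @ phi.ravel()).reshape(s.shape) - s
    resid[~fm] = 0.0
    rel = float(np.abs(resid).max()) / max(float(np.abs(s).max()), 1e-300)
    if scale > 0 and rel > max(tol, 1e-9):
        raise ConvergenceError(
            f"Poisson residual {rel:.3e} exceeds tolerance", history=[rel]
        )
    return PotentialField(grid, phi, metadata={"residual": rel, "projected_mean": imbalance})


def _face_gradient(phi: np.ndarray, grid: StructuredGrid):
    """Face-normal gradient of a cell-centred scalar (zero through solids)."""
    nx, ny = grid.n_axial, grid.n_transverse
    gx = np.zeros((nx + 1, ny))
    gx[1:-1] = (phi[1:] - phi[:-1]) / grid.dx
    if grid.axial_periodic:
        gx[0] = gx[-1] = (phi[0] - phi[-1]) / grid.dx
    gy = np.zeros((nx, ny + 1))
    gy[:, 1:-1] = (phi[:, 1:] - phi[:, :-1]) / grid.dy
    gx[~x_face_fluid(grid)] = 0.0
    gy[~y_face_fluid(grid)] = 0.0
    return gx, gy


def project_solenoidal(
    raw: SteadyVelocityField, tol_div: float | None = None
) -> tuple[SteadyVelocityField, PotentialField]:
    """Remove the non-solenoidal component: v_L = v*_L - grad(Phi).

    Returns the solenoidal field (with its exactly divergence-free face
    representation attached) and the potential.  A field that already
    satisfies the divergence tolerance is passed through unchanged with
    Phi = 0 (the projection is idempotent).
    """
    grid = raw.grid
    uf, vf = raw.faces()
    div_before = face_divergence(uf, vf, grid)
    max_before = float(np.abs(div_before).max())
    tol = tol_div if tol_div is not None else default_tol_div(grid, raw.max_speed())
    diag = {"max_div_before": max_before, "tol_div": tol}
    if max_before <= tol:
        out = SteadyVelocityField(
            grid, raw.u.copy(), raw.v.copy(), "lagrangian_solenoidal",
            uf, vf, {**raw.metadata, **diag, "max_div_after": max_before},
        )
        return out, PotentialField(grid, np.zeros_like(raw.u), metadata=diag)

    pot = solve_poisson(div_before, grid)
    gx, gy = _face_gradient(pot.phi, grid)
    uf2, vf2 = uf - gx, vf - gy
    div_after = face_divergence(uf2, vf2, grid)
    diag["max_div_after"] = float(np.abs(div_after).max())
    diag["mean_abs_div_before"] = float(np.abs(div_before[grid.fluid_mask]).mean())
    diag["mean_abs_div_after"] = float(np.abs(div_after[grid.fluid_mask]).mean())
    u, v = centers_from_faces(uf2, vf2, grid)
    out = SteadyVelocityField(
        grid, u, v, "lagrangian_solenoidal", uf2, vf2,
        {**raw.metadata, **diag},
    )
    pot.metadata.update(diag)
    return out, pot
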