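"""Solute transport solvers and dispersion diagnostics.

Two solvers share one conservative finite-volume core:

* :func:`integrate_full_transport` — the benchmark: advection by the full
  time-periodic velocity field v(x, t),
      dc/dt + v . grad c = kappa lap c,
  resolving the fast concentration oscillations over many cycles;
* :func:`integrate_reduced_transport` — the reduced model: advection by a
  *steady* mean field (the solenoidal mean Lagrangian velocity v_L, or the
  cycle-averaged Eulerian velocity <v> for the comparison model),
      dc/dt + v_L . grad c = kappa lap c.

Advection uses dimension-split, flux-limited upwind reconstruction
(third-order Koren limiter by default, or second-order minmod); each 1-D
sweep is conservative and positivity-preserving for CFL <= 1.  Diffusion is
explicit with zero-flux walls.  The axial ends of the (tiled, open) domain
are outflow boundaries: solute crossing them is lost from the domain but
accumulated in a mass ledger, so the global balance closes to round-off.

Dispersion diagnostics follow the effective-diffusivity picture of Taylor
dispersion: the cross-sectionally integrated profile C(x, t), its centre of
mass and variance, and the hydrodynamic diffusivity
kappa_H(t) = [sigma^2(t) - sigma^2(0)] / (2 t).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from .errors import ConservationError, InputError, StabilityError
from .fields import PeriodicVelocityField, SteadyVelocityField
from .grid import SPAN_CM, StructuredGrid

_TINY = 1e-300


@dataclass(frozen=True)
class TransportParams:
    """Numerical parameters for a transport integration.

    diffusivity : molecular diffusivity kappa, m^2/s (0 allowed: the
        diffusionless variant).
    dt : time step, s (the reduced solver shrinks it if the drift CFL
        requires; the full solver raises instead, since its dt must stay
        commensurate with the velocity phase sampling).
    scheme : ``"limited_upwind_3rd"`` (Koren) or ``"upwind_2nd"`` (minmod).
    t_end : integration horizon, s.
    snapshot_interval : cadence (s) at which full c(x, t) snapshots are
        retained; the initial and final states are always kept.
    """

    diffusivity: float = 7e-10
    dt: float = 0.01
    scheme: str = "limited_upwind_3rd"
    t_end: float = 60.0
    snapshot_interval: float = 1.0
    cfl_limit: float = 0.95

    def __post_init__(self):
        if self.diffusivity < 0:
            raise InputError("diffusivity must be >= 0")
        if self.dt <= 0 or self.t_end <= 0:
            raise InputError("dt and t_end must be positive")
        if self.scheme not in ("limited_upwind_3rd", "upwind_2nd"):
            raise InputError(f"unknown scheme {self.scheme!r}")

    @property
    def kappa_cm2s(self) -> float:
        return self.diffusivity * 1e4


@dataclass
class ConcentrationHistory:
    """Snapshots of c(x, t) on the (tiled) transport grid with a mass ledger."""

    grid: StructuredGrid
    times: list = dataclass_field(default_factory=list)
    snapshots: list = dataclass_field(default_factory=list)
    outflow_mass: list = dataclass_field(default_factory=list)  # cumulative, mL
    metadata: dict = dataclass_field(default_factory=dict)

    def append(self, t: float, c: np.ndarray, outflow: float):
        self.times.append(float(t))
        self.snapshots.append(c.copy())
        self.outflow_mass.append(float(outflow))

    @property
    def initial_mass(self) -> float:
        return float(self.snapshots[0].sum()) * self.grid.cell_volume

    def domain_mass(self, k: int = -1) -> float:
        return float(self.snapshots[k].sum()) * self.grid.cell_volume

    def mass_closure_error(self) -> float:
        """Max relative error of (domain mass + cumulative outflow) vs initial."""
        m0 = self.initial_mass
        if m0 == 0:
            return 0.0
        worst = 0.0
        for k in range(len(self.times)):
            worst = max(
                worst, abs(self.domain_mass(k) + self.outflow_mass[k] - m0) / m0
            )
        return worst

    def min_concentration(self) -> float:
        return float(min(snap.min() for snap in self.snapshots))


@dataclass
class LongitudinalProfile:
    """Cross-sectionally integrated solute C(x, t) = int c ds, cm^2."""

    x: np.ndarray
    times: np.ndarray
    C: np.ndarray  # (n_times, n_axial)

    def at_time(self, t: float) -> np.ndarray:
        k = int(np.argmin(np.abs(self.times - t)))
        return self.C[k]


@dataclass
class DispersionMetrics:
    """Bolus centre of mass, variance and hydrodynamic diffusivity vs time."""

    table: pd.DataFrame  # columns: t, x_bar, sigma2 [, kappa_H]
    stroke_volume: float | None = None
    epsilon: float | None = None

    def sigma(self, t: float) -> float:
        k = int(np.argmin(np.abs(self.table["t"].to_numpy() - t)))
        return float(np.sqrt(self.table["sigma2"].iloc[k]))


# ---------------------------------------------------------------------------
# initial condition

def gaussian_bolus(
    grid: StructuredGrid, center: float = 5.6, width_param: float = 0.5
) -> ConcentrationHistory:
    """Gaussian bolus c(x) = exp[-(x - center)^2 / width_param], uniform
    across the cross-section (zero in solid cells).

    The defaults reproduce the canonical injection used throughout the
    package: a bolus centred at x = 5.6 cm with width parameter 0.5 cm^2.
    """
    x0 = grid.origin[0]
    x1 = x0 + grid.segment_length
    if not (x0 < center < x1):
        raise InputError(f"bolus centre {center} outside domain ({x0}, {x1})")
    if width_param <= 0:
        raise InputError("width parameter must be positive")
    c = np.exp(-((grid.x_centers - center) ** 2) / width_param)
    c2d = np.where(grid.fluid_mask, c[:, None], 0.0)
    hist = ConcentrationHistory(grid, metadata={"center": center, "width": width_param})
    hist.append(0.0, c2d, 0.0)
    return hist


# ---------------------------------------------------------------------------
# finite-volume core

def _limiter(r: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "limited_upwind_3rd":      # Koren
        return np.maximum(0.0, np.minimum(np.minimum(2.0 * r, (1.0 + 2.0 * r) / 3.0), 2.0))
    return np.maximum(0.0, np.minimum(1.0, r))  # minmod (2nd-order upwind)


def _sweep_axis(c, vel_face, spacing, dt, fluid, scheme, periodic=False):
    """One conservative 1-D advection sweep along axis 0.

    ``c``: (n, m) cell values; ``vel_face``: (n+1, m) face-normal velocity
    (zero on solid faces; boundary faces are open: outflow takes the donor
    cell value at first order, inflow carries zero concentration).
    Returns the updated field and the mass flux (per face area) that left
    through the two open boundary faces.
    """
    n = c.shape[0]
    cfl = np.max(np.abs(vel_face)) * dt / spacing
    if cfl > 1.0:
        raise StabilityError(f"advective CFL {cfl:.2f} > 1 in a sweep")
    # pad with one ghost cell each side
    if periodic:
        cp = np.concatenate([c[-2:], c, c[:2]], axis=0)
        fp = np.concatenate([fluid[-2:], fluid, fluid[:2]], axis=0)
    else:
        cp = np.concatenate([c[:1] * 0, c[:1] * 0, c, c[-1:] * 0, c[-1:] * 0], axis=0)
        fp = np.concatenate(
            [fluid[:1] * False] * 2 + [fluid] + [fluid[:1] * False] * 2, axis=0
        )
    # face f sits between cp[f+1] and cp[f+2] for f = 0..n
    c_dn2, c_dn1 = cp[:-3], cp[1:-2]      # two cells on the low side
    c_up1, c_up2 = cp[2:-1], cp[3:]       # two cells on the high side
    f_dn2, f_dn1 = fp[:-3], fp[1:-2]
    f_up1, f_up2 = fp[2:-1], fp[3:]

    pos = vel_face >= 0
    d = c_up1 - c_dn1                      # downwind - upwind jump across face
    d_safe = np.where(np.abs(d) > _TINY, d, _TINY)
    r_pos = (c_dn1 - c_dn2) / d_safe
    r_neg = (c_up2 - c_up1) / d_safe
    phi_pos = _limiter(r_pos, scheme)
    phi_neg = _limiter(r_neg, scheme)
    # fall back to first order where the wide stencil leaves the fluid
    phi_pos = np.where(f_dn2 & f_dn1 & f_up1, phi_pos, 0.0)
    phi_neg = np.where(f_up2 & f_up1 & f_dn1, phi_neg, 0.0)
    c_face = np.where(
        pos, c_dn1 + 0.5 * phi_pos * d, c_up1 - 0.5 * phi_neg * d
    )
    flux = vel_face * c_face
    if not periodic:
        # open ends: donor value leaves, nothing enters
        flux[0] = np.where(vel_face[0] < 0, vel_face[0] * c[0], 0.0)
        flux[-1] = np.where(vel_face[-1] > 0, vel_face[-1] * c[-1], 0.0)
    c_new = c - (dt / spacing) * (flux[1:] - flux[:-1])
    if periodic:
        out = np.zeros(c.shape[1:])
    else:
        out = dt * (np.maximum(flux[-1], 0.0) - np.minimum(flux[0], 0.0))
    return c_new, out


def _diffuse(c, grid: StructuredGrid, kappa, dt):
    """Explicit conservative diffusion step, zero flux on solids and walls."""
    fm = grid.fluid_mask
    fx = np.zeros((grid.n_axial + 1, grid.n_transverse))
    link_x = fm[:-1] & fm[1:]
    fx[1:-1] = np.where(link_x, -kappa * (c[1:] - c[:-1]) / grid.dx, 0.0)
    fy = np.zeros((grid.n_axial, grid.n_transverse + 1))
    link_y = fm[:, :-1] & fm[:, 1:]
    fy[:, 1:-1] = np.where(link_y, -kappa * (c[:, 1:] - c[:, :-1]) / grid.dy, 0.0)
    return c - dt * ((fx[1:] - fx[:-1]) / grid.dx + (fy[:, 1:] - fy[:, :-1]) / grid.dy)


def _advance(c, uf, vf, grid, kappa, dt, scheme, out_accum):
    """One unsplit explicit step: limited fluxes in both directions are
    computed from the same state and applied together, then diffusion.

    Keeping the update unsplit avoids the spurious compression/expansion a
    dimension-split scheme suffers next to stair-step obstacles, where the
    1-D divergence of each velocity component is large even though the full
    field is solenoidal; positivity then requires the *cellwise* CFL sum
    |u| dt/dx + |v| dt/dy <= 1 (checked by the callers).
    """
    dcx, out_x = _sweep_axis(c, uf, grid.dx, dt, grid.fluid_mask, scheme)
    dcy, _ = _sweep_axis(c.T, vf.T, grid.dy, dt, grid.fluid_mask.T, scheme)
    c = dcx + dcy.T - c
    if kappa > 0:
        c = _diffuse(c, grid, kappa, dt)
    out_accum += float(out_x.sum()) * grid.dy * SPAN_CM
    return c, out_accum


def max_cfl_sum(uf, vf, grid: StructuredGrid, dt: float) -> float:
    """Max over cells of |u| dt/dx + |v| dt/dy (face maxima per cell)."""
    ucell = np.maximum(np.abs(uf[:-1]), np.abs(uf[1:]))
    vcell = np.maximum(np.abs(vf[:, :-1]), np.abs(vf[:, 1:]))
    return float(np.max(ucell / grid.dx + vcell / grid.dy) * dt)


def _check_diffusion_stability(kappa, grid, dt):
    if kappa > 0:
        lam = kappa * dt * (1.0 / grid.dx**2 + 1.0 / grid.dy**2)
        if lam > 0.25:
            raise StabilityError(
                f"explicit diffusion number {lam:.3f} > 0.25; reduce dt"
            )


def _run(c0_hist, grid, face_supplier, params, dt, n_steps, label):
    kappa = params.kappa_cm2s
    _check_diffusion_stability(kappa, grid, dt)
    c = c0_hist.snapshots[0].copy()
    hist = ConcentrationHistory(
        grid,
        metadata={
            **c0_hist.metadata,
            "variant": label,
            "scheme": params.scheme,
            "dt": dt,
            "kappa_cm2s": kappa,
        },
    )
    hist.append(0.0, c, 0.0)
    out = 0.0
    snap_every = max(1, int(round(params.snapshot_interval / dt)))
    for n in range(n_steps):
        uf, vf = face_supplier(n)
        c, out = _advance(c, uf, vf, grid, kappa, dt, params.scheme, out_accum=out)
        if (n + 1) % snap_every == 0 or n == n_steps - 1:
            hist.append((n + 1) * dt, c, out)
    return hist


# ---------------------------------------------------------------------------
# public solvers

def integrate_full_transport(
    field: PeriodicVelocityField,
    c0: ConcentrationHistory,
    params: TransportParams,
    n_segments: int | None = None,
) -> ConcentrationHistory:
    """Benchmark transport under the full oscillatory velocity field.

    A field given on a periodic segment is tiled axially (``n_segments``
    defaults to the grid's own replication count) to build the open domain;
    the velocity within a step is the linear-in-time blend of the two
    bracketing phase snapshots evaluated at the step midpoint.
    """
    if field.grid.axial_periodic:
        field = field.tile(n_segments)
    grid = field.grid
    if grid.n_axial != c0.grid.n_axial or grid.n_transverse != c0.grid.n_transverse:
        raise InputError("initial condition grid does not match the tiled field")
    dt = params.dt
    n_steps = int(round(params.t_end / dt))
    if abs(n_steps * dt - params.t_end) > 1e-9 * max(params.t_end, 1.0):
        raise InputError("dt must divide t_end")
    n_ph = field.n_phases
    T = field.period
    ufs = [field.snapshot_faces(k)[0] for k in range(n_ph)]
    vfs = [field.snapshot_faces(k)[1] for k in range(n_ph)]
    # a time blend of two snapshots is facewise bounded by the snapshots,
    # so the worst cellwise CFL sum over the cycle can be checked up front
    cfl = max(max_cfl_sum(u, v, grid, dt) for u, v in zip(ufs, vfs))
    if cfl > params.cfl_limit:
        raise StabilityError(
            f"cellwise CFL sum {cfl:.2f} exceeds {params.cfl_limit} at "
            f"dt={dt}; reduce the time step"
        )

    def faces(n):
        phase = ((n + 0.5) * dt % T) / T * n_ph
        k0 = int(phase) % n_ph
        w = phase - int(phase)
        k1 = (k0 + 1) % n_ph
        return (
            (1 - w) * ufs[k0] + w * ufs[k1],
            (1 - w) * vfs[k0] + w * vfs[k1],
        )

    return _run(c0, grid, faces, params, dt, n_steps, "full_dns")


def integrate_reduced_transport(
    mean_field: SteadyVelocityField,
    c0: ConcentrationHistory,
    params: TransportParams,
    n_segments: int | None = None,
) -> ConcentrationHistory:
    """Reduced (steady-advection) transport under a mean velocity field.

    Accepts the solenoidal mean Lagrangian velocity (the reduced model) or
    the cycle-averaged Eulerian velocity (the comparison model, labelled
    ``comparison_eulerian`` in the output metadata).  A raw, unprojected
    Lagrangian field is rejected: its divergence acts as a non-physical
    distribution of sinks and sources that violates solute conservation.
    """
    if mean_field.role == "lagrangian_raw":
        raise ConservationError(
            "raw (unprojected) mean Lagrangian velocity rejected: project it "
            "first (spinaldrift.helmholtz.project_solenoidal) to remove the "
            "sink/source divergence term"
        )
    if mean_field.role not in ("lagrangian_solenoidal", "eulerian_mean"):
        raise InputError(f"unsupported mean-field role {mean_field.role!r}")
    if mean_field.grid.axial_periodic:
        mean_field = mean_field.tile(n_segments)
    grid = mean_field.grid
    if grid.n_axial != c0.grid.n_axial or grid.n_transverse != c0.grid.n_transverse:
        raise InputError("initial condition grid does not match the tiled field")
    uf, vf = mean_field.faces()
    dt = params.dt
    vmax_x = float(np.max(np.abs(uf)))
    vmax_y = float(np.max(np.abs(vf)))
    limit = params.cfl_limit / max(vmax_x / grid.dx + vmax_y / grid.dy, _TINY)
    if dt > limit:
        dt = limit
    n_steps = max(1, int(np.ceil(params.t_end / dt)))
    dt = params.t_end / n_steps

    label = (
        "comparison_eulerian" if mean_field.role == "eulerian_mean" else "reduced"
    )
    hist = _run(c0, grid, lambda n: (uf, vf), params, dt, n_steps, label)
    hist.metadata["dt_requested"] = params.dt
    hist.metadata["dt_used"] = dt
    return hist


# ---------------------------------------------------------------------------
# diagnostics

def longitudinal_profile(history: ConcentrationHistory) -> LongitudinalProfile:
    """C(x, t): concentration integrated over the cross-section, cm^2."""
    grid = history.grid
    C = np.stack(
        [snap.sum(axis=1) * grid.dy * SPAN_CM for snap in history.snapshots]
    )
    return LongitudinalProfile(
        x=grid.x_centers, times=np.asarray(history.times), C=C
    )


def dispersion_stats(profile: LongitudinalProfile) -> DispersionMetrics:
    """Centre of mass x_bar(t) and variance sigma^2(t) of C(x, t).

    Trapezoidal quadrature over the axial stations; raises on zero mass.
    """
    x = profile.x
    rows = []
    for k, t in enumerate(profile.times):
        C = profile.C[k]
        mass = np.trapezoid(C, x)
        if mass <= 0:
            raise InputError(f"zero solute mass at t = {t}; statistics undefined")
        x_bar = np.trapezoid(x * C, x) / mass
        sigma2 = np.trapezoid((x - x_bar) ** 2 * C, x) / mass
        rows.append((t, x_bar, sigma2))
    return DispersionMetrics(pd.DataFrame(rows, columns=["t", "x_bar", "sigma2"]))


def hydrodynamic_diffusivity(metrics: DispersionMetrics) -> DispersionMetrics:
    """Effective (Taylor-type) diffusivity kappa_H(t), cm^2/s.

    Evaluated with the secant rule kappa_H(t) = [sigma^2(t) - sigma^2(0)]/(2t)
    (NaN at t = 0).
    """
    tab = metrics.table.copy()
    t = tab["t"].to_numpy()
    s2 = tab["sigma2"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        tab["kappa_H"] = np.where(t > 0, (s2 - s2[0]) / (2 * t), np.nan)
    return DispersionMetrics(tab, metrics.stroke_volume, metrics.epsilon)


def profile_deviation(a: LongitudinalProfile, b: LongitudinalProfile, t: float) -> float:
    """Integrated |C_a - C_b| dx at time t, divided by the total solute mass.

    The measure used to quantify the effect of molecular diffusion: the
    local difference between two runs integrated over the domain relative
    to the amount of solute present.
    """
    Ca = a.at_time(t)
    Cb = b.at_time(t)
    mass = np.trapezoid(Ca, a.x)
    if mass <= 0:
        raise InputError("zero solute mass; deviation undefined")
    return float(np.trapezoid(np.abs(Ca - Cb), a.x) / mass)


def linear_interpolate(x: float, xs, ys) -> float:
    """Piecewise-linear interpolation helper (used e.g. to interpolate
    in-vitro hydrodynamic-diffusivity measurements to a stroke volume)."""
    return float(np.interp(x, np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)))
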