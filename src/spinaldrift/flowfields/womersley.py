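"""Exact oscillatory laminar flow in a plane channel (Womersley-type).

For a harmonic pressure gradient at angular frequency w the axial velocity in
a channel of half-width h is

    u(eta, t) = Re[ u_hat(eta) e^{i w t} ],
    u_hat(eta) ∝ 1 - cosh(L eta) / cosh(L),   L = h sqrt(i w / nu),

with eta the transverse coordinate scaled to [-1, 1].  Here the profile of
each harmonic is normalised so that its cross-sectional integral reproduces
the corresponding harmonic of the prescribed flow rate exactly; the zero
mode is the parabolic Poiseuille profile.  |L| is the Womersley number times
sqrt(i): for |L| -> 0 the profile reduces to the quasi-steady parabola.

This closed form is the oracle against which the numerical oscillatory
solver is validated.
"""

from __future__ import annotations

import numpy as np

from ..errors import InputError
from ..fields import PeriodicVelocityField
from ..grid import SPAN_CM, StructuredGrid
from ..waveforms import FluidParams, FlowRateWaveform


def _harmonic_profile(eta: np.ndarray, lam: complex) -> np.ndarray:
    """Profile f(eta)/mean(f) with f = 1 - cosh(lam*eta)/cosh(lam)."""
    if abs(lam) < 1e-6:          # quasi-steady limit: parabola
        return 1.5 * (1.0 - eta**2)
    f = 1.0 - np.cosh(lam * eta) / np.cosh(lam)
    mean = 1.0 - np.tanh(lam) / lam
    return f / mean


def womersley_axial_profile(
    y: np.ndarray,
    t: float | np.ndarray,
    waveform: FlowRateWaveform,
    fluid: FluidParams,
    height: float,
    y0: float = 0.0,
) -> np.ndarray:
    """Closed-form axial velocity u(y, t) (cm/s) for the given flow rate.

    ``y`` are transverse positions (cm) in a channel occupying
    ``[y0, y0 + height]``; the flow rate is decomposed into harmonics and
    each contributes its exact oscillatory profile.
    """
    h = height / 2.0
    eta = (np.asarray(y, dtype=float) - y0 - h) / h
    omega = 2 * np.pi / waveform.period
    nu = fluid.nu_cm2s
    area = height * SPAN_CM
    t = np.asarray(t, dtype=float)
    u = np.zeros(np.broadcast_shapes(eta.shape, t.shape + eta.shape))
    for k, q_hat in waveform.harmonics():
        if k == 0:
            u = u + (q_hat / area) * _harmonic_profile(eta, 0.0)
        else:
            lam = h * np.sqrt(1j * k * omega / nu)
            prof = _harmonic_profile(eta, lam)
            phase = np.exp(1j * k * omega * t)
            u = u + (np.multiply.outer(phase, prof) * (q_hat / area)).real
    return u


def womersley_channel_flow(
    grid: StructuredGrid,
    waveform: FlowRateWaveform,
    fluid: FluidParams,
    n_phases: int = 100,
    multi_harmonic: str = "reject",
) -> PeriodicVelocityField:
    """Analytic oscillatory channel flow sampled on ``grid``.

    The grid must be an obstacle-free plane channel.  ``multi_harmonic``
    selects what to do when the waveform carries more than one oscillatory
    harmonic: ``"decompose"`` sums the per-harmonic closed forms,
    ``"reject"`` raises.
    """
    if np.any(grid.solid_mask):
        raise InputError("Womersley flow requires an obstacle-free channel")
    if multi_harmonic not in ("reject", "decompose"):
        raise InputError("multi_harmonic must be 'reject' or 'decompose'")
    harmonics = waveform.harmonics()
    n_osc = sum(1 for k, _ in harmonics if k > 0)
    if n_osc > 1 and multi_harmonic == "reject":
        raise InputError(
            f"waveform has {n_osc} oscillatory harmonics; pass "
            "multi_harmonic='decompose' to superpose their exact profiles"
        )

    times = np.arange(n_phases) * waveform.period / n_phases
    prof = womersley_axial_profile(
        grid.y_centers, times, waveform, fluid, grid.height, grid.origin[1]
    )  # (n_phases, ny)
    nx, ny = grid.n_axial, grid.n_transverse
    u = np.repeat(prof[:, None, :], nx, axis=1)
    v = np.zeros_like(u)
    uf = np.repeat(prof[:, None, :], nx + 1, axis=1)
    vf = np.zeros((n_phases, nx, ny + 1))

    q_num = u[:, 0, :].sum(axis=1) * grid.dy * SPAN_CM
    q_tgt = waveform(times)
    scale = max(np.max(np.abs(q_tgt)), 1e-300)
    meta = {
        "max_flow_rate_error": float(np.max(np.abs(q_num - q_tgt)) / scale),
        "womersley_number": grid.height
        / 2.0
        * np.sqrt(2 * np.pi / waveform.period / fluid.nu_cm2s),
    }
    return PeriodicVelocityField(grid, waveform.period, u, v, uf, vf, meta)
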