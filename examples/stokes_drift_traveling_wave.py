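"""Eulerian vs Lagrangian mean motion in a traveling wave.

Builds the canonical manufactured flow u = U cos(kx - wt) (made solenoidal
by a stream function), whose cycle-averaged Eulerian velocity is exactly
zero, and shows that fluid particles nevertheless drift at the classical
Stokes-drift rate U^2 k / (2 w) — the kinematic effect at the heart of the
reduced dispersion model.
"""

import numpy as np

import spinaldrift as sd

U, k, T = 0.05, np.pi, 1.0      # cm/s, 1/cm, s
omega = 2 * np.pi / T

grid = sd.channel_grid(128, 16, 2.0, 0.25, axial_periodic=True)
wave = sd.make_manufactured_wave_flow(grid, U, k, T, kind="traveling")

mean = sd.cycle_average(wave)
drift = sd.stokes_drift_asymptotic(wave)
traj, status = sd.advect_particle(wave, (0.5, 0.125), n_cycles=5)

closed_form = U**2 * k / (2 * omega)
print(f"wave: U = {U} cm/s, k = {k:.3f} 1/cm, eps = U k/w = {U * k / omega:.4f}")
print(f"cycle-averaged Eulerian velocity : {np.abs(mean.u).max():.2e} cm/s (zero)")
print(f"Stokes drift (asymptotic formula): {drift.u[64, 8]:.6f} cm/s")
print(f"Stokes drift (closed form)       : {closed_form:.6f} cm/s")
print(f"particle drift over 5 cycles     : {(traj[-1, 0] - traj[0, 0]) / 5:.6f} cm/s ({status})")
print()
print("A fixed probe sees zero mean flow, yet every fluid particle drifts")
print("along the wave: transport models built on the Eulerian mean alone")
print("miss this contribution entirely.")
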