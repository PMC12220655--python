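"""Mean Lagrangian velocity of the obstructed cervical-channel analogue.

Solves the oscillatory flow through the obstructed channel at physiological
dimensionless stroke length (eps = 0.439), tracks fluid particles for one
cycle from 20 seeding phases, deposits v*_L = delta_x / T on the grid, and
removes the non-solenoidal component by the Helmholtz projection — the
drift field that drives the reduced transport model.
"""

import numpy as np

import spinaldrift as sd
from spinaldrift.scenarios import build_waveform, scenario_config

cfg = scenario_config("channel_obstructed")
grid = cfg.geometry.build_grid()
waveform = build_waveform(cfg)
v_s, eps = sd.stroke_volume_and_epsilon(waveform, grid.fluid_volume())
print(f"segment volume {grid.fluid_volume():.3f} mL, V_s = {v_s:.3f} mL, eps = {eps:.3f}")

field, controller = sd.solve_oscillatory_channel(
    grid, waveform, sd.FluidParams(), dt=cfg.flow.dt
)
print(f"flow: periodic after {controller.n_cycles} cycles, "
      f"peak |u| = {np.abs(field.u).max():.2f} cm/s")

particles = sd.lagrangian_mean_from_trajectories(field)
ok = (particles.table["status"] == "ok").mean()
raw = sd.scatter_to_grid(particles)
v_lagr, potential = sd.project_solenoidal(raw)
v_eul = sd.cycle_average(field)

print(f"particles: {len(particles.table)} samples, {100 * ok:.1f}% completed the cycle")
print(f"divergence of v*_L : {v_lagr.metadata['max_div_before']:.2e} 1/s")
print(f"divergence of v_L  : {v_lagr.metadata['max_div_after']:.2e} 1/s (projected)")
print(f"max |v_L|  = {np.hypot(v_lagr.u, v_lagr.v).max():.3f} cm/s")
print(f"max |<v>|  = {np.hypot(v_eul.u, v_eul.v).max():.3f} cm/s")
print()
print("The oscillatory velocity is ~2 cm/s, but the net drift a fluid")
print("particle accumulates per cardiac cycle is two orders smaller —")
print("this steady drift field is what disperses the drug over minutes.")
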