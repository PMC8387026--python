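"""Simulate a calibrated export-system variant under a pulsed LED protocol.

Builds the slow-cycling preset, integrates the photocycle + transport model
under the standard LED box protocol (2 s pulses, 1 s breaks, 70% intensity)
followed by dark recovery, and prints the steady states and observable
half-times.  The N/C ratio is the nuclear-to-cytoplasmic amount ratio — the
core observable of nuclear-export experiments.
"""

import numpy as np

from lexykit import (LightProtocol, LightSegment, live_preset,
                     observable_half_time, simulate, steady_state)

params = live_preset("live-iLEXYs")
print("calibrated rates (1/min):", params.to_dict())

u_dark, r_dark = steady_state(params, 0.0)
u_lit, r_lit = steady_state(params, 1.0)
print(f"dark steady state: lit fraction {u_dark:.4f}, N/C ratio {r_dark:.2f}")
print(f"lit  steady state: lit fraction {u_lit:.4f}, N/C ratio {r_lit:.2f}")

t_ind = observable_half_time(params, "induction") * 60
t_rec = observable_half_time(params, "recovery")
print(f"induction ratio half-time: {t_ind:.1f} s; recovery: {t_rec:.1f} min")

# 10 min pulsed LED illumination, then 60 min dark recovery
protocol = LightProtocol((
    LightSegment(0.0, 10.0, intensity=0.7, pulse_period_s=3.0, duty=2.0 / 3.0),
    LightSegment(10.0, 70.0, intensity=0.0),
))
grid = np.linspace(0.0, 70.0, 701)
trace = simulate(params, protocol, grid)
i_end_light = np.searchsorted(grid, 10.0)
print(f"N/C ratio after 10 min LED light: {trace.ratio[i_end_light]:.2f} "
      f"(depleted from {trace.ratio[0]:.2f})")
print(f"N/C ratio after 60 min dark:      {trace.ratio[-1]:.2f} "
      "(partial recovery; full recovery takes several recovery half-times)")
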