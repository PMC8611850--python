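"""Evaluate the two instrument forward models on bench-style readings.

Surface tension comes from the pull-off (ring tear-off) voltage drop;
viscosity from a falling ball's terminal speed with wall and depth
corrections to Stokes drag.
"""

from magmeta.instruments import (
    surface_tension_from_instrument,
    viscosity_from_falling_ball,
)

# pull-off: voltmeter reads 5.2 V just before the film breaks, 3.1 V after;
# conversion coefficient K = 40, ring diameters 33 and 35 mm
sigma = surface_tension_from_instrument(u1=5.2, u2=3.1, k=40.0, d1=0.033, d2=0.035)
print(f"surface tension sigma = {sigma:.5f} N/m")

# falling ball: steel ball (7800 kg/m^3, d = 2 mm) in fertilizer solution
# (1000 kg/m^3), cylinder D = 50 mm, depth H = 0.4 m, terminal speed 50 mm/s
eta = viscosity_from_falling_ball(
    rho=7800, rho0=1000, d=0.002, big_d=0.05, h=0.4, v=0.05
)
print(f"viscosity eta         = {eta:.2f} mPa·s")
print("(the wall/depth corrections keep eta below the uncorrected Stokes value)")
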