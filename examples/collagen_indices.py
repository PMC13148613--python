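"""Collagen meridional indices: D-period, I6/I5 and overlap fraction.

Builds a noiseless meridional profile of a fresh collagen fibril
(D = 66.727 nm, overlap fraction x = 0.46), fits the fifth- and sixth-
order reflections, and inverts Bragg's law and the two-phase step-density
model.  The same chain runs per scan point inside the full pipeline.
"""

import math

import numpy as np

from scansaxs import (compute_d_period, default_grid, fit_peak,
                      solve_overlap_fraction)
from scansaxs.collagen import order_weight, order_window
from scansaxs.simulate import collagen_sigma

D_TRUE, X_TRUE = 66.727, 0.46
grid = default_grid()
q = grid.q_centers

profile = 0.5 * q ** -3.0
for n in range(1, 11):
    c = 2 * math.pi * n / D_TRUE
    s = collagen_sigma(n)
    w = float(order_weight(n, X_TRUE))
    profile += 600.0 * w * np.exp(-0.5 * ((q - c) / s) ** 2) / (s * math.sqrt(2 * math.pi))

fit5 = fit_peak(q, profile, order_window(5))
fit6 = fit_peak(q, profile, order_window(6))

d5 = compute_d_period(5, fit5.center)
ratio = fit6.area / fit5.area
x_hat = solve_overlap_fraction(fit5.area, fit6.area)

print(f"D-period from fifth order:  {d5:.3f} nm   (true {D_TRUE})")
print(f"I6/I5 area ratio:           {ratio:.4f}")
print(f"overlap fraction O/D:       {x_hat:.4f}    (true {X_TRUE})")
print("\nAn intact hydrated fibril sits at O/D ~ 0.46; dehydration lowers")
print("the overlap fraction and drives I6/I5 up sharply (7.2 at x = 0.42).")
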