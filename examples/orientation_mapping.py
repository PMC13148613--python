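"""Fit the azimuthal cosine model and recover fiber orientations.

Fits I(phi) = a_sym + a_asym cos 2(phi - theta_s) to each collagen point's
azimuthal profile in the first-order collagen band and compares the
recovered scattering direction theta_s with the simulator's orientation
field.  The degree of orientation a_asym/a_sym is 0 for isotropic points
and approaches 1 for strongly aligned fibers.
"""

import numpy as np

from scansaxs import analyze_scan, make_ground_truth, simulate_reduced_scan

gt = make_ground_truth("unprocessed", 16, 16, seed=7)
scan = simulate_reduced_scan(gt, seed=8)
df = analyze_scan(scan).table.data

sub = df.dropna(subset=["col_theta_s"])
errors = []
for _, row in sub.iterrows():
    d = abs(row.col_theta_s - gt.theta[int(row.row), int(row.col)]) % 180.0
    errors.append(min(d, 180.0 - d))

print(f"collagen points fitted:            {len(sub)}")
print(f"median |theta_hat - theta_true|:   {np.median(errors):.2f} deg "
      "(sector width is 22.5 deg)")
print(f"median degree of orientation:      {sub.col_degree.median():.3f}")
print("\nThe angular error stays well below half a sector because the")
print("2-phi Fourier component interpolates between the 16 sectors.")
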