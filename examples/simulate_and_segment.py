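"""Simulate a tissue scan and segment it into regions.

Builds a small synthetic scanning-SAXS raster of fresh (unprocessed)
tissue, computes the low-q intensity exponent per point and labels each
point collagen / muscle / other / background, then prints the confusion
against the simulator's ground truth.
"""

import numpy as np

from scansaxs import (analyze_scan, make_ground_truth, simulate_reduced_scan)
from scansaxs.scan import REGION_NAMES

gt = make_ground_truth("unprocessed", 16, 16, seed=1)
scan = simulate_reduced_scan(gt, seed=2)
result = analyze_scan(scan)

print("region counts (predicted):")
print(result.table.data["region"].value_counts().to_string())

agree = (result.region == gt.label).mean()
print(f"\nagreement with ground-truth labels: {agree:.1%}")
print("(collagen points have a positive intensity exponent from the rising")
print(" first-order peak edge; muscle diffuse scatter sits near -3; the")
print(" 'other' connective component falls below -4)")

for code, name in REGION_NAMES.items():
    sel = result.region == code
    if sel.any():
        alphas = result.alpha[sel & np.isfinite(result.alpha)]
        if alphas.size:
            print(f"  {name:10s} median exponent {np.median(alphas):+.2f}")
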