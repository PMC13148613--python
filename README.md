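# scansaxs

Scanning small-angle X-ray scattering (sSAXS) analysis of soft tissue.

In an sSAXS experiment a specimen is raster-scanned with a focused X-ray
beam and a full 2D scattering pattern is recorded at every grid point.
For skeletal-muscle tissue each pattern carries two structural
fingerprints: the meridional Bragg orders of the collagen fibril axial
repeat (the ~67 nm *D*-period) in the connective tissue, and the
equatorial (1,0)/(1,1) doublet of the hexagonal myofilament lattice in
the muscle fibers.  `scansaxs` turns a stack of such patterns — reduced
to 16 azimuthal sectors × ~1200 *q* bins per point — into per-point
structural maps and cross-sample statistics:

- **Segmentation** — the power-law exponent of *I(q)* in the window
  0.085–0.095 nm⁻¹ (the rising edge of the first-order collagen peak)
  classifies each point as collagen (positive slope), muscle, other
  connective structure, or background, with an enhanced sixth-order
  reflection as fallback when processing destroyed the first order.
- **Orientation** — the π-periodic cosine model
  *I*(φ) = *a*<sub>sym</sub> + *a*<sub>asym</sub> cos 2(φ − θ<sub>s</sub>)
  fitted per point and *q* band; degree of orientation
  *a*<sub>asym</sub>/*a*<sub>sym</sub>; HSV orientation maps.
- **Collagen indices** — Gaussian fits of the fifth/sixth meridional
  orders give the *D*-period via Bragg's law *D* = 2π*n*/*q*<sub>n</sub>,
  peak widths, the dehydration-sensitive ratio *I*₆/*I*₅, and the
  overlap fraction *x* = *O*/*D* by inverting the two-phase step-density
  model *I*<sub>n</sub> ∝ sin²(π*nx*)/(π*n*)² (≈ 0.46 in intact hydrated
  fibrils).
- **Muscle lattice** — equatorial doublet fits give *d*₁,₀ = 2π/*q*₁,₀,
  *d*₁,₁, the lattice constant *a* = 2*d*₁,₀/√3, and *I*₁,₁/*I*₁,₀
  (low at rest, strongly elevated in rigor).
- **Statistics** — box-plot summaries and two-sided Mann–Whitney
  rank-sum comparisons against a declared reference sample, with the
  usual star mapping (\* ≤ 0.05, \*\* ≤ 0.01, \*\*\* ≤ 0.001).
- **Simulator** — a forward model with known ground truth (region
  mosaics, smooth orientation fields, step-model order weights, Poisson
  noise) and preservation-method presets (unprocessed, dehydrated,
  tough-resin, paraffin, cryo) for validating every stage.

The library is the primary interface (see `examples/`); a thin CLI
(`scansaxs simulate|reduce|analyze|summarize|compare|render`) covers
shell use.

## Worked example

```python
from scansaxs import (make_ground_truth, simulate_reduced_scan,
                      analyze_scan, compare_samples)

tables = {}
for preset in ("unprocessed", "dehydrated"):
    gt = make_ground_truth(preset, 16, 16, seed=5)
    scan = simulate_reduced_scan(gt, seed=6)
    tables[preset] = analyze_scan(scan).table

report = compare_samples(tables, reference="unprocessed",
                         parameters=["D5", "i6_over_i5", "overlap_fraction"])
print(report[["parameter", "median", "median_ref",
              "percent_change", "stars"]].to_string(index=False))
```

prints

```
       parameter    median  median_ref  percent_change stars
              D5 65.439364   66.702152       -1.893175   ***
      i6_over_i5  7.953830    0.494118     1509.701584   ***
overlap_fraction  0.419076    0.460099       -8.916103   ***
```

The dehydrated specimen shows the expected signature: a shrunken
*D*-period, a sharply elevated *I*₆/*I*₅, and an overlap fraction pulled
from the hydrated 0.46 toward 0.42 — all flagged highly significant
against the fresh reference.

Each script in `examples/` exercises one capability (segmentation,
orientation mapping, collagen indices, muscle lattice, sample
comparison) on a small simulated scan and prints what the numbers mean.

## Data format

Scans live in a single HDF5 container per scan: datasets
`/scan/intensity` `[ny, nx, 16, n_q]`, `/scan/q`, `/scan/phi`,
`/scan/transmission`, attributes `exposure_s`, `step_um`.  Missing bins
carry a negative sentinel and are excluded from every fit.  Per-point
results are written as CSV with a stable documented column order;
maps as PNG.
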