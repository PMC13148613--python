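# Methods

This note documents the models, estimators, numerical choices and known
limitations of `scansaxs`.

## Data model

A reduced scan is a 4D array `[ny, nx, n_seg, n_q]` of counts per
exposure: each raster point holds an azimuthally regrouped pattern with
`n_seg = 16` uniform sectors (centers at (k+½)·22.5°, counterclockwise
from the detector +x axis) and `n_q = 1200` radial bins.  The default
*q* grid spans 0.05–1.0 nm⁻¹ so that collagen meridional orders up to
*n* = 10 (*D* ≈ 67 nm puts order 10 at 0.94 nm⁻¹) remain on-grid for
per-order prevalence tables.  Missing or masked bins are stored as a
negative sentinel and excluded from every fit, so masks survive
serialization.  Raster metadata defaults (25 µm step, 100 ms exposure)
describe typical scanning conditions and only matter for normalization.

Azimuthal regrouping of raw frames uses the exact flat-detector relation
*q* = (4π/λ) sin(½ atan(r/L)) and assigns each unmasked pixel to the
(sector, *q*) bin containing its (*q*, φ); the bin statistic is the
**mean** of pixel counts, which keeps bins comparable across unequal
solid angles.  Solid-angle, polarization and flat-field corrections are
out of scope.  Transmission is a beamstop-scatter proxy: ROI counts over
an empty-beam reference, clipped to (0, 1] because the proxy can exceed
the reference through noise.  Normalization divides per point by
(transmission × exposure) and is idempotent via a flag.

## Segmentation

The per-point statistic is the least-squares slope α of log *I* vs
log *q* over 0.085–0.095 nm⁻¹ of the azimuthally averaged profile (at
least 4 positive bins required).  This window sits on the rising edge of
the first-order collagen peak, so collagen shows α > 0 while diffuse
muscle scatter sits near the background power-law exponent and a third
connective-tissue component — three broad peaks near *q* = 0.075, 0.16,
0.245 nm⁻¹, with the window in the decaying flank of the first —
falls far lower.  Labels: background where transmission ≥ 0.99 (empty
beam) or α is unfittable; collagen where α ≥ 0 **or** a sixth-order
reflection is detected (the fallback for samples whose first order was
destroyed by processing); other where α < −4; muscle otherwise.  Only
the ordering of the cuts is physically fixed; the numeric thresholds are
configuration values that must be validated on real data before
scientific use.

## Orientation

The azimuthal intensity in a *q* band (collagen 0.085–0.11 nm⁻¹,
myofibrils 0.231–0.367 nm⁻¹) is fitted with
*I*(φ) = *a*<sub>sym</sub> + *a*<sub>asym</sub> cos 2(φ − θ<sub>s</sub>).
With all 16 sectors valid the parameters are the discrete 2φ Fourier
component (*a*<sub>sym</sub> = mean, c₂ = (2/N) Σ I e^(−2iφ),
*a*<sub>asym</sub> = |c₂|, θ<sub>s</sub> = −arg c₂ / 2 mod 180°), which
is exactly the least-squares solution by orthogonality on a uniform
grid; with masked sectors an explicit least-squares fit on
{1, cos 2φ, sin 2φ} is used instead, and the two coincide in the
complete case (asserted to 1e−9).  θ<sub>s</sub> is reported in
[0, 180) matching the 180° colourwheel; isotropic points (a<sub>asym</sub>
below machine precision relative to a<sub>sym</sub>) report NaN.
The degree of orientation *a*<sub>asym</sub>/*a*<sub>sym</sub> lies in
[0, 1] for any realistically spread azimuthal vector; for pathologically
concentrated vectors (most power in the 2φ harmonic, e.g. a single hot
sector) the Fourier amplitude can mathematically reach twice the mean —
such inputs do not arise from the π-periodic kernels of fibrous scatter.
Collagen's long axis lies along the meridional scattering direction;
the myofibril axis is perpendicular to its equatorial direction (+90°).

Orientation maps encode θ<sub>s</sub> as hue; in hue–value mode
saturation is 1 and value is *a*<sub>asym</sub>, in HSV mode value is
*a*<sub>sym</sub> and saturation *a*<sub>asym</sub>.  Channels rescale
to the 1st–99th percentiles by default — explicit and configurable,
since fixed scaling choices change what a map appears to show.

## Peak fitting

All reflections (collagen orders, muscle doublet) share one fitter: in a
*q* window, a power law *A q^b* is fitted in log–log space to the outer
20% of bins on each flank and subtracted; a single Gaussian is then
fitted to the residual with lmfit (bounds: center inside the window,
σ between half a bin and the window width).  A peak is **visible** when
(i) the amplitude is at least `snr_min` (default 3) times the post-fit
residual RMS, with an absolute floor so a numerically-zero residual
cannot promote a numerically-zero amplitude, (ii) the center is strictly
inside the window, and (iii) σ ≥ 1.5 *q* bins.  The width floor encodes
the *q*-binning resolution limit: on noise-only profiles the free fit
otherwise latches single-bin spikes (≈8% of windows, all with σ at the
half-bin bound), while genuine reflections are an order of magnitude
wider.  Widths narrower than the binning limit are indeterminate, which
also means fitted FWHMs carry a positive bias bounded by about one bin.

If the first-pass center lands inside a background flank — a reflection
shifted toward a window edge, as embedding shrinkage does at several
percent — the window is recentred on that estimate once and the fit
repeated, so the background flanks genuinely exclude the peak.  Default
search windows are 2π*n*/*D*₀ · (1 ± 0.06) with *D*₀ = 67 nm; order 1 is
excluded from *D* estimation (too few bins across a steep background)
and order 3 as well (overlap with the muscle (1,1) window), though both
are still fitted for prevalence tables.

## Collagen structural indices

*D* = 2π*n*/*q*<sub>n</sub> per order (Bragg).  *I*₆/*I*₅ is the ratio
of integrated intensities (Gaussian areas — the quantities the
two-phase model predicts).  The overlap fraction *x* = *O*/*D* solves

    r = I₆/I₅ = (5/6)² · sin²(6πx) / sin²(5πx),

the consecutive-order ratio of the two-phase (gap/overlap step-density)
weights *w*<sub>n</sub>(x) = sin²(π*nx*)/(π*n*)².  The solver scans
[0.35, 0.55] at 1e−4 and refines every sign change by bisection to
1e−12.  The equation has several roots; the returned one is the root
closest to a `reference` (default 0.46, the intact hydrated fibril —
operationalizing "structurally reasonable").  Two regimes deserve note:
at *x* = 0.5 the sixth order is extinguished (symmetric gap/overlap), so
r = 0 maps to 0.5 directly; at *x* = 0.4 the **fifth** order is
extinguished and r diverges — no inversion exists at that pole, and for
*x* below it the default reference selects the branch above the pole, so
recovering a known off-reference branch requires passing that knowledge
as `reference`.  Root-finding precision (|x̂ − x| < 1e−5 across
[0.38, 0.498]) and branch selection are therefore separate concerns, and
are tested separately.

Per-sample prevalence tables report, per order *n*: the median over
points of the per-point area ratio *I*<sub>n</sub>/*I*₁ (points with
both orders visible), and the fraction of collagen points with a visible
order-*n* peak.  Normalization is per-point (not per-sample median); the
choice is flagged for review as either reading is defensible.

## Muscle lattice

Per muscle point, the profile along the equatorial direction (the
opposite sector pair nearest θ<sub>eq</sub> from the myofibril band; on
exact half-way ties the pair on the positive side is taken so that
orthogonal directions select orthogonal pairs) is fitted in two
non-overlapping windows (defaults 0.14–0.21 and 0.24–0.34 nm⁻¹,
bracketing vertebrate-muscle spacings; configurable because embedding
shifts spacings by over 30%).  Spacings are *d* = 2π/*q*; the hexagonal
lattice constant is *a* = 2*d*₁,₀/√3, and |d₁,₀/(d₁,₁√3) − 1| ≥ 0.1
flags a geometrically inconsistent pair.  *I*₁,₁/*I*₁,₀ is an area
ratio.  Collagen's third order can contaminate the (1,1) window, which
is why the doublet is fitted only on points labeled muscle.

## Statistics

Distributions are summarized box-plot style (linear-interpolation
quartiles, whiskers at the most extreme datum within 1.5 IQR, outlier
count).  Sample comparisons use the two-sided Mann–Whitney rank-sum
test: the populations are unpaired pixel sets of unequal size, for which
a signed-rank test is undefined (a paired signed-rank variant exists for
genuinely paired inputs).  Exact enumeration is used when both samples
have ≤ 8 observations and no cross-sample ties; otherwise the
tie-corrected, continuity-corrected normal approximation.  The two
branches agree to about 0.01 in *p* at n = 8 (the theoretical worst case
over all U values is 0.042, at atypical mid-range statistics); the
continuity correction is kept because dropping it quadruples the error.
Fully tied data yields *p* = 1.  Stars: \* ≤ 0.05, \*\* ≤ 0.01,
\*\*\* ≤ 0.001, else ns; significance is read as *p* ≤ 0.05.  No
multiple-testing correction is applied.  Type-I error at nominal
α = 0.05 is verified at 0.05 ± 0.02 over 10³ null simulations.

## Simulator

The generator draws a region mosaic (quantile-thresholded smoothed
Gaussian noise; default interior fractions 45% collagen / 35% muscle,
remainder "other"; a background frame of empty-beam points), a smooth
orientation field θ(x, y) = ½ atan2 of two smoothed noise fields, and
parameter fields equal to preset values with 0.2% relative spatial
jitter.  Expected counts per point, sector and bin:

    I = S q^(−β) + A_c Σₙ mₙ wₙ(x) N(q; 2πn/D, σₙ) K(φ; θ, κ)
      + [muscle] A_m [N(q; 2π/d₁₀, σ_m) + ρ N(q; 2π/d₁₁, σ_m)] K(φ; θ+90°, κ_m)
      + floor

with *N* a **unit-area** Gaussian — so integrated peak areas are exactly
proportional to the step-model weights and the analysis-side *I*₆/*I*₅
and *x̂* recover the generated truth; unit-amplitude peaks would bias the
ratio by σ₆/σ₅ = √(6/5) — and K(φ; θ, κ) = exp(κ(cos 2(φ−θ) − 1)), a
π-periodic von-Mises-style kernel that reduces to the cosine model at
small κ and stays positive at large κ.  Defaults: background S = 0.5,
β = 3, floor 2 counts, σₙ = 0.0025 √n nm⁻¹ (slight order broadening,
keeping 10 orders resolved on the 1200-bin grid), σ_m = 0.006 nm⁻¹,
κ = κ_m = 1, collagen amplitude 600 (fifth-order peak ≈ 110 counts over
a ≈5-count background, SNR well above 10), muscle amplitude 5 (an order
of magnitude weaker than collagen, matching the tissue contrast), and
d₁₁ = d₁₀/√3 exactly.  The "other" component adds three broad
(σ = 0.012) Gaussians at 0.075/0.16/0.245 nm⁻¹.  Counts are
Poisson-sampled at a preset count scale; everything is deterministic
given (preset, shape, seed).

Presets encode preservation effects as parameter shifts: `unprocessed`
(D = 66.727 nm, x = 0.46, resting-like ρ = 0.4), `dehydrated` (D −2%,
x = 0.42, first order suppressed, orders ≥ 7 amplified, muscle doublet
destroyed), `tough_resin` (D −3.64%, all orders ×3 from staining
contrast, spacings −5%, elevated ρ), `paraffin` (x = 0.435, low orders
damped, muscle spacings −30% — deliberately outside the default fit
windows, as real embedding shifts are), `cryo` (reference collagen,
ρ = 1.6, half the count rate).  Where the source ranges are printed as
ranges, presets use midpoints.  Orders 5 and 6 keep unit multipliers in
every preset: a multiplier on the solver's own orders would make the
generated overlap fraction unidentifiable from *I*₆/*I*₅, and the
enhanced sixth order at low *x* already emerges from the step model.

What the simulator does **not** emulate: absolute intensity calibration,
radiation damage, Kapton/air scatter, beamstop geometry, detector gaps,
crossing fiber populations, and spatially correlated (non-Poisson)
noise.  Passing recovery tests therefore demonstrates estimator
correctness under the stated statistical model, not performance on any
particular beamline's artifacts.

## Problem sizes and determinism

Test and acceptance runs use desk-scale problems chosen once: 60×60
points for end-to-end parameter recovery (median D̂₅ within 0.2%,
x̂ within ±0.005, d̂₁₀ within 0.3% of truth), 18–20 px mosaics across 5
seeds for preservation-ordering and confusion checks, 10³ profiles for
false-positive and type-I calibration.  All randomness flows through
explicit integer seeds; rerunning any stage on the same inputs produces
byte-identical CSVs.

## Known limitations

- Segmentation thresholds are simulator-validated defaults, not values
  fitted to real tissue.
- The overlap-fraction model is a two-phase axial density approximation;
  cross-linking or mechanical stress also move *x*, so it is a hydration
  index only under the stated interpretation.
- Per-order prevalence normalization (per-point vs per-sample) and the
  amplitude-vs-area reading of "integrated intensities" are documented
  choices (area chosen), flagged for review against reference data.
- The (1,1) window is not spectrally unmixed from collagen's third
  order; muscle fits rely on segmentation being correct.
- FWHM estimates are biased upward by up to about one *q* bin.
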