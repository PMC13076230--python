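# Methods

This note documents the measurement models in `pillarmyelin`, their
assumptions, the defaults that matter, and what the synthetic-data
generator does and does not emulate.

## Coordinate and projection conventions

Voxels are indexed `(z, y, x)` with coordinates at pixel centers;
physical position is `index × calibration`, and z index 0 is the gel
base. A maximum-intensity projection over `[z_lo, z_hi)` includes a
slice when its *center* lies in that half-open interval, which makes
projections over adjacent ranges combine exactly (the per-pixel max
over `[a,b)` and `[b,c)` equals the max over `[a,c)`) and avoids double
counting at range boundaries.

Two projections drive the analysis: full height for nuclei and cell
bodies, and base-excluded for myelin. The base-exclusion height is not
a physical constant of the assay — it depends on where cell bodies and
debris sit on the gel — so it is a parameter, default **4 µm**
(`z_lo`), and every run records the value used.

## Array geometry and swelling

An array spec carries the mold-side diameter *D*, edge-to-edge spacing
*d*, height *h* and a swelling fraction *s*; the realized (immersed)
diameter is `D(1+s)` and the lattice pitch is realized diameter plus
*d*. Polyacrylamide features swell ≈26% in PBS, so 26% is the default
*s*. The swelling factor recovered from an image is
`(measured − D)/D`, reported as mean ± s.d. over unflagged pillars.

Pillar detection is deliberately simple because the arrays are regular
by construction: Otsu threshold (overridable by a fixed value) →
connected components → centroids, then an axis-aligned least-squares
lattice fit that assigns row/col indices by nearest node (iterated to
convergence, collisions resolved by smallest residual). Lattice sites
with no disc are reported as absent rather than dropped. Diameter is
the equivalent-disc diameter `√(4·area/π)` of the component, which is
robust to boundary pixelation; footprints touching the image border are
flagged and excluded from swelling statistics. Fewer than four
candidate pillars is treated as "no grid".

## Angular coverage and the wrapping score

Per pillar, an annulus from the measured pillar radius outward
(default width **2 µm**) is divided into **72** angular sectors (5°),
each supersampled 4× in angle and 8× in radius by bilinear
interpolation. A sector's intensity statistic is the mean over its
angular sub-samples of the **radial maximum**: the myelin ring is much
thinner than the annulus, and averaging over the full annulus area
would dilute a genuine ring below any sensible field threshold, whereas
the radial maximum measures angular occupancy independently of ring
thickness. A sector is covered when this statistic exceeds the field
threshold (Otsu on the base-excluded MBP projection per field,
overridable; a blank projection yields an infinite threshold and zero
coverage). Coverage *c* is the covered fraction of sectors; the maximum
gap is the longest circular run of uncovered sectors.

The ordinal score maps coverage to {0, 1, 2, 3}. The endpoints are
fixed by the scheme (0 = no myelin, 3 = closed ring); the interior bin
edges are not published anywhere, so they are an explicit, configurable
choice, default **0.05 / 0.45 / 0.95**, chosen symmetric about the
class midpoints. Score 3 additionally requires the largest angular gap
to be at most **18°** (one ~5% arc of the circumference): a
near-complete ring that does not close is demoted to 2. All summaries
should be reported together with the bins used.

Ring thickness is the median over covered sectors of the radial FWHM of
the above-threshold profile outward from the pillar edge. On unblurred
renders this recovers the rendered thickness to within a pixel; under
blur, the FWHM of a ring comparable in width to the blur kernel is
inflated by the convolution, so thickness estimates from low-resolution
data should be treated as upper bounds. Sub-pixel thickness is reported
as one pixel with a resolution-limit flag. The g-ratio uses the
measured (swollen) pillar diameter: `g = D/(D + 2t)`, since the
formula's *D* is the wrapped structure's actual inner diameter.

## Field statistics

Nuclei are counted on the full-height projection: Otsu threshold,
distance-transform watershed seeded at h-maxima (suppression 1 px) to
split touching somata, minimum object area **12 µm²**. Per-field
metrics: score counts and percentages, fully wrapped (score 3) pillars
per cell = count₃/n_cells, and pillar:cell ratio. Pillars flagged
out-of-bounds by the wrap stage are excluded from every denominator and
their number is reported (`n_excluded`) so no exclusion is silent; zero
cells leaves per-cell metrics undefined (NaN, flagged) while counts are
still reported.

Condition-level fold change is the mean of per-field values divided by
the mean of the reference condition's fields (not the mean of per-field
ratios); this choice is recorded in output metadata. Group comparisons
are standard one-way ANOVA with Tukey HSD, refusing degenerate input
(single group, groups of one field, zero overall variance).

## AFM force curves and Hertz fit

Processing chain: moving-average smoothing (default **11** samples) →
straight-line baseline fit on the pre-contact segment → contact-point
estimation → cantilever-bending correction `δ = (z − z₀) − F/k` → least
squares for *E* in `F = (4/3)·E/(1−ν²)·√R·δ^{3/2}` (linear in *E* once
z₀ is fixed), with ν = 0.5 for incompressible hydrogels and *R* half
the bead diameter (12.5 or 25 µm supported).

The contact point is found by a two-segment model — flat baseline plus
Hertz-shaped rise — scored by total squared residual over a coarse grid
of candidate z₀ and refined by bounded scalar minimisation. Instrument
software normally does this step opaquely; this is the reproducible
replacement. A curve whose baseline-subtracted force never exceeds
5× the baseline noise s.d. is rejected as contact-free. The fit uses
indentations up to `δ_max_fit`, default **10% of the bead radius**
(the shallow-indentation validity range of the Hertz model; the depth
used in the original workflow is not recorded anywhere, hence a
parameter). Gel stiffness is the arithmetic mean ± s.d. of the grid of
indentations (typically 3×3) on that gel.

## Lamellar profiles

Layer counting finds intensity peaks with prominence above **20%** of
the profile's dynamic range and spacing ≥ **5 nm** (repeats below
~4 nm are taken as unresolvable), after a light low-pass at half the
minimum spacing so single-sample noise spikes cannot masquerade as
lamellae. Total myelin thickness is the distance between the outer
half-maximum crossings of the lamellar *band envelope*: the raw
modulated trace dips below half maximum at every inter-lamellar valley,
which would truncate the band by roughly half a period per side, so the
trace is first smoothed with a moving average one repeat period wide
(period estimated from the detected peak spacing; for a single lamella,
its own FWHM stands in). Per-lamella thickness is total thickness over
layer count by definition; the thickness-vs-layer-count OLS slope is an
independent estimate of the same repeat distance. Transects are taken
as input; extracting them from 2D micrographs is out of scope.

## Synthetic data: what it emulates and what it does not

The image generator renders anti-aliased cylinders (pillar channel),
annular arcs of configured coverage and radial thickness placed only
above the base-exclusion height (myelin channel; one contiguous arc per
pillar by default, optionally split, uniformly random start angle), and
ellipsoidal nuclei (4 µm lateral, 2.5 µm axial semi-axes) near the
base. Default degradations: per-slice Gaussian blur σ **0.4 µm**,
background **5%** of peak, Gaussian read noise **2%** of peak, optional
Poisson counting noise — plausible confocal SNR, all overridable and
all engineering choices (acquisition settings are not published).
Identical seeds give bit-identical output.

The force-curve generator solves the bending-coupled Hertz system
self-consistently per sample (Newton iteration), samples 1,024 piezo
positions spanning a ≥2 µm baseline plus ≥2 µm of indentation, and
annotates true *E* and z₀. The lamella generator superimposes a cosine
modulation (one peak per layer) on a smoothed top-hat envelope of width
`n_layers × period`, so truth thickness is exact by construction; a
single lamella is rendered as one unmodulated band.

Passing recovery tests on these inputs demonstrates that the
measurement operators are correct and unbiased under the stated model;
it does not demonstrate robustness to out-of-focus haze, anisotropic
PSFs, uneven illumination, autofluorescence, cell-body occlusion of
rings, or TEM sectioning artefacts — none of which are simulated.

## Problem sizes

The test suite and the acceptance script run on deliberately small
instances chosen to exercise every code path at comfortable numerical
margins: 4×4 to 15×15 pillar fields at 0.25 µm/px, 9 force curves per
gel per stiffness grade, three lamellar "sections" of 120 pillars with
14 measured transects each, and 1,000 null replicates for the ANOVA
calibration.

## Known limitations

- Scoring operates on the 2D projection, as in standard practice for
  vertical-pillar assays; no 3D surface reconstruction is attempted.
- Ring thickness (hence g-ratio) is biased upward when the ring width
  is comparable to the optical blur.
- The lattice fit assumes an axis-aligned rectangular grid; rotated or
  irregular layouts are out of scope.
- No bottom-effect (substrate thickness) correction or viscoelastic
  model in the AFM fit.
- Nuclei counting assumes roughly convex nuclei; heavily clumped
  cultures will undercount even with watershed splitting.
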