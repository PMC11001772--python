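# Methods

## Chamber modes and nodal sets

The stationary surface displacement of a vibrated round chamber is modelled
as a single Bessel mode, `ζ(r, θ) = J_m(α_mn · r/R)·cos(mθ)`, where `α_mn`
is the n-th positive zero of `J_m` and `R` (mm) is the radius of the
simulated domain.  The square chamber uses the antisymmetric superposition
of the degenerate (m, n) and (n, m) cosine modes on `[0, lx]²`, which
always carries the main diagonal in its nodal set.  No fluid dynamics is
solved: the drive frequency (54 Hz) and vertical acceleration (1.2 g) that
select a mode experimentally are recorded as protocol metadata only, and
the simulation is parameterized directly by the mode indices.  Defaults:
round m=0, n=4, R=21 mm; square m=5, n=1, lx=15 mm; 512×512 grids.

A modelling choice worth making explicit: with `R` read as the domain
*radius*, the m=0, n=4 mode has exactly four concentric nodal circles in
(0, R] — the boundary circle `r = R` (where `J_0(α_04) = 0` identically) is
counted.  Reading the 21 mm figure as a diameter would leave only two
interior circles, which contradicts the four-ring condensate the geometry
is meant to produce, so radius it is.

Bessel zeros are taken from scipy's `jn_zeros` (the accuracy contract,
|J_m(α)| < 1e-10, is what matters, not the provider); the test suite checks
them against an independent bisection oracle built on a power-series /
integral-representation evaluation of `J_m`.

Nodal curves are traced as zero-level contours by marching squares with
sub-cell linear interpolation (`skimage.measure.find_contours`), using the
unmasked analytic field so the boundary circle is traceable; contour points
beyond `R + pitch` are discarded.  A contour counts as a nodal circle when
it closes, its radial spread is below max(3% of its radius, one pitch), and
it is at least one pitch away from circles already found.  The default
nodal tolerance for the boolean mask is 2% of the field maximum.

The accumulation map converts a mode shape into a cell-density ridge
`exp(−(d/s)²)` with `d = ζ/|∇ζ|` (a first-order signed distance to the
nodal set) and `s` set so the ridge FWHM equals the requested width.  The
linearization makes the realized FWHM accurate to ~5–7% at ring curvature;
the map is normalized to integrate to 1 over the chamber.

## Synthetic images

Cells are opaque discs (default radius 7.5 µm — an endothelial cell body of
~15 µm) rendered into a binary mask, blurred with a Gaussian of
σ = cell_radius/2 as a point-spread stand-in, and scaled to 16-bit.  Area
fractions are defined on the binary mask, which is what a GFP+ area
measurement thresholds out.

Placement is a homogeneous binomial point process: the disc count is fixed
at `round(λA)` with `λ = −ln(1−f)/a_disc`, so the Boolean-model coverage
`1 − exp(−λa)` matches the programmed fraction `f` exactly in expectation.
Fixing the count (instead of drawing it Poisson) removes the dominant
count-fluctuation term from the realized-fraction variance — necessary for
the generator contract that realized fractions match programmed ones within
2% relative at ≥1024² px — while leaving placement spatially uniform
(quadrat dispersion ≈ 1).

For the pattern image, extra discs are added on the nodal band *dilated by
one cell radius*, so coverage is uniform across the band with no edge
deficit.  Cells condensed at the band edge consequently protrude up to two
cell radii outside it; the recorded off-pattern fraction therefore excludes
a guard zone of that width (the full complement is also recorded).  For the
rings geometry the band is placed by the exact radial distance to the
analytically known nodal radii; for the honeycomb the `ζ/|∇ζ|` distance
estimate is used.  The default image is 2048² px at 2.5 µm/px (a ~5 mm
desk-scale stand-in for a full-chamber overview scan; the chamber is mapped
to 95% of the image half-extent, so the boundary ring stays inside the
frame).

Ribbon networks are random smooth walks (radius of curvature ~80 px, larger
than the widest ribbons so they do not fold onto themselves) dilated to a
per-ribbon width drawn from a normal truncated at one pixel.  Day presets
(13.1 ± 24.7, 10.6 ± 18.9, 4.1 ± 9.5 µm for days 1/3/5) parameterize that
distribution; because of the truncation and because thicker ribbons cover
more area, the appropriate recovery comparison is the thickness-map mean
against the *area-weighted realized* width recorded in the truth sidecar,
not the nominal mean.  Crossings additionally inflate the map mean by a few
percent.

The proteome generator draws per-protein log2 baselines from
Normal(20, 2), adds ±|Normal(2, 0.3)| shifts to the programmed up/down
subsets in the patterned group, and Normal(0, 0.25) per-sample residuals;
abundances are `2^log2`, strictly positive.  Defaults: 4000 proteins, 3
samples per group, 643 up / 261 down.  The generator does not model missing
values, intensity-dependent variance, or correlated proteins — conclusions
about those failure modes cannot be drawn from these tests.

What passing tests show, and what they do not: recovery on these synthetics
demonstrates that the measurement chain is unbiased and correctly
implemented under its own assumptions (disc-shaped cells, uniform
background, rect-profile bands, complete log-normal abundance tables).
Real images add uneven illumination, out-of-focus light and touching-cell
texture; real proteomes add missingness and heavier tails.  None of those
are emulated.

## Morphometrics

* **Radial profiles** average intensity over half-open annuli `[k·dr,
  (k+1)·dr)` about the image center (the synthetic pattern is centered by
  construction; a mask-centroid refinement is available for off-center
  data).  Empty annuli are carried as NaN, never zero-filled.  An `r_max`
  bound excludes the partially-sampled image corners.  Near the center an
  annulus holds only a few pixels and its mean is noisy, so peak detection
  on intensity profiles is run at `dr` = 2 px and prominence 0.25 of the
  dynamic range (the library default is 0.1 for clean profiles).
* **Ring FWHM** measures the width between half-maximum crossings (linear
  interpolation) against a baseline set by the mean of the two flanking
  valleys.  On synthetic rings the measured width is the programmed band
  plus one cell diameter of edge spill (~100 → ~110 µm).
* **ROI density enhancement** follows the 3-ROI protocol: square ROIs with
  side equal to the pattern line width, three per location (on-pattern /
  distal / proximal / random), on-pattern centered on the detected ring at
  angles {0°, 120°, 240°}, distal/proximal offset radially by ±1.5 line
  widths, random evaluated at the same positions on the stationary control.
  Enhancement = (mean on-pattern / mean random − 1)·100.  At 5% background
  coverage a single triplet of 100 µm ROIs contains ~9 background cells, so
  one triplet estimate of a ~440% enhancement carries an SD near 190
  points; benchmark recovery therefore averages the (unchanged) per-triplet
  protocol over rotated placements around the ring and over replicate image
  pairs.  The detected ring radius is refined by an iterated center of mass
  over a window twice the band width (a window the size of the band leaves
  noise-dominated weights after baseline subtraction).
* **Local thickness** assigns each foreground pixel the diameter (µm) of
  the largest disc fully contained in the foreground that covers it.
  Implementation: Euclidean distance transform → pruning of centers whose
  disc is contained in a neighbor's (r_p ≥ r_q + |p−q|) → painting of the
  surviving discs with exact integer squared radii and open-disc membership
  (|p−c|² < r²).  This is exactly the brute-force definition (the test
  suite verifies equality against direct enumeration on random masks), at a
  cost close to the distance ridge rather than all foreground pixels.
  Statistics default to foreground pixels only; the include-zero convention
  is provided because images whose field of view is mostly background give
  very different means under the two conventions (SDs larger than the mean
  are the signature of the all-pixels convention).
* **Orientation** uses the structure tensor of cubic-B-spline image
  gradients with a Gaussian window of σ = 4 px; orientation is
  `½·atan2(2⟨f_x f_y⟩, ⟨f_y²⟩ − ⟨f_x²⟩)` and pixels with tensor trace below
  30% of the maximum are excluded.  The 180×1° histogram is smoothed with a
  5-bin periodic moving average and normalized to sum 1.  On degenerate
  single-angle fixtures the smoothing creates a flat 5-bin plateau whose
  argmax sits at its left edge; rotation equivariance (shift of the peak)
  is exact nonetheless.  The FFT high-pass zeroes the centered disc of
  radius 10 cycles/image by default (DC always removed).

## Differential expression

Per protein, a two-sample t-test on log2 abundances, BH adjustment across
all proteins, and a direction call (up/down/ns) at q < 0.05 with no
fold-change cutoff by default (an optional |log2FC| cutoff is available).
The default is the *pooled* equal-variance t: at n = 3 per group the
Welch–Satterthwaite df collapses toward 2 whenever the two tiny variance
estimates disagree, which costs ~8% sensitivity at the generator's own
settings even though the true variances are equal; the pooled test (df = 4)
reaches the intended >0.99 sensitivity at |log2FC| = 2 with residual SD
0.25, and matches what the common proteomics front-ends run by default.
Welch remains available (`equal_var=False`).

A consequence of BH at q < 0.05 with ~3100 null proteins and ~940
rejections is ~36 expected false discoveries, split evenly by sign; the
smaller (down) class is therefore recovered a few percent high on average
(≈278 vs 261 programmed), while the up class absorbs the same absolute
excess well inside 5%.  This is a property of the FDR criterion, not a
defect of the test, and the recovery experiments report it as measured.

PCA scores come from the SVD of the protein-centered samples×proteins
matrix (equivalent to the covariance eigen-decomposition), with the
largest-|loading| sign convention.  Top-k selection takes the k smallest q
(ties broken by larger |log2FC|) among significant proteins and orders rows
and columns by average-linkage hierarchical clustering on Euclidean
distances of autoscaled values.

## Pipeline, determinism and problem sizes

Every stochastic stage derives an explicit sub-seed from the run seed; no
global RNG state is used, and the same (config, seed) reproduces reports
byte-identically.  The default orchestrated run uses deliberately compact
sizes — 1024² px images at 5 µm/px, 384² px networks at 0.5 µm/px, a
2000-protein table — chosen so a full run completes in seconds while every
measured quantity remains well-resolved (bands ≥ 20 px wide, ribbons ≥ 8 px).
The benchmark script uses the full-scale settings (2048² px at 2.5 µm/px,
4000 proteins, six replicate image pairs for the enhancement recovery,
three noisy images for the FWHM).

## Known limitations

* The mode model is stationary and linear; mode competition, meniscus
  effects and streaming flows are out of scope.
* The `ζ/|∇ζ|` distance estimate behind the accumulation map (and the
  honeycomb band) carries a few-percent width error and a few-µm centering
  error at strong curvature; the rings generator sidesteps this with exact
  radial distances.
* Ribbon networks are geometric stand-ins — no vessel topology, lumen, or
  migration dynamics; thickness recovery is only meaningful against the
  area-weighted realized widths.
* The orientation histogram's absolute peak position on near-degenerate
  distributions is quantized by the smoothing plateau (±2 bins).
* The DE stage assumes complete tables; the min-valid filter for real
  tables with missing values is provided but not exercised by the
  generators.
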