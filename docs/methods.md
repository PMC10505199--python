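# Methods

This note documents the models, conventions and design choices behind the
package. It states no empirical result that the test suite and analysis
drivers do not themselves compute.

## Shape descriptors

The p-fold shape function of a V-sided polygon is

γ_p = Σ_{v=1..V} |r_v|^p e^{i p φ_v} / Σ_v |r_v|^p,

with r_v the v-th vertex relative to the polygon's centre of mass and φ_v
its polar angle. |γ_p| ≤ 1 by the triangle inequality; the phase divided by
p is the cell's p-fold orientation, reported in [0, 2π/p). γ_p is
translation-invariant, scale-invariant, and rotation-covariant (the phase
shifts by pα under rotation by α). The phase is numerically ill-conditioned
when |γ_p| ≈ 0 (a regular hexagon has no meaningful 2-fold orientation).

**Centre-of-mass convention.** "Centre of mass" is ambiguous for a polygon:
the area centroid and the arithmetic mean of the vertices differ for
irregular cells. The package defaults to the area centroid (the physical
lamina centre); the vertex mean is available via
`gamma_p(..., reference="vertex-mean")` and the `--com` CLI flag, and the
choice is recorded in CLI output metadata.

**Shape index.** p₀ = P/√A; ≥ 2√π for any shape, ≈3.7224 for a regular
hexagon, 4.0 for a square.

**R_cc.** The mean cell–cell distance is the mean centroid distance over
unordered neighbour pairs with both cells interior, each pair counted once.
Averaging per pair (not per cell) weights each junction equally; the
alternative per-cell average differs only at second order in the degree
distribution and is not exposed.

## Coarse-graining and the crossover

Γ_p(r, R) is the plain average of γ_p over cells whose centroid lies
*strictly* inside the disk (Θ(0) = 0, so a centroid exactly on the rim is
excluded — relevant only on lattice fixtures). Sampling points form a
square grid with spacing exactly R_cc/2 spanning a centred field of view
(default 124 × 124 μm, clipped to the data box); the radius ladder is
R_cc/2, R_cc, … up to half the field-of-view diagonal. Grid points whose
disk is empty are missing values and are excluded from the grid mean of
|Γ_p|; magnitudes are taken before averaging at every stage where an
ensemble magnitude is reported.

Border cells (polygons touching the field boundary, which are clipped and
therefore biased) never contribute γ_p values; grid points near the border
keep whatever interior cells fall inside their disk. There is no edge
correction and no minimum disk count beyond N_disk ≥ 1; the resulting mild
edge bias is accepted rather than modelled.

The crossover scale R× is the first radius interval where
Δ(R) = |Γ₆|−|Γ₂| changes sign from positive to non-positive, located by
linear interpolation on the ladder and reported in units of R_cc. Profiles
that never change sign return no crossover together with a diagnostic
regime ("hexatic-dominated" / "nematic-dominated at all scales"). Ensembles
can be summarised either per monolayer (each fixture's own R×) or by
pooling seed-averaged profiles (`pooled_crossover`); the pooled estimator
is far less noisy in the shallow tail where the profiles nearly touch, and
is what the ensemble-level analyses use.

## Topological defects

The director θ = Arg(Γ_p)/p is defined where |Γ_p| > 0; the winding number
of a grid plaquette sums the four corner-to-corner differences, each
wrapped to the principal branch (−π/p, π/p]. The symmetric branch makes the
charge antisymmetric under field conjugation; winding numbers are snapped
to the nearest multiple of 1/p with tolerance 10⁻⁶ and anything farther is
an error, not a rounding. Plaquettes with a missing or zero-magnitude
corner are skipped. Defect densities are reported per 100 cells (counts of
both signs together; positive and negative totals are also emitted), and
the "density at the crossover" is evaluated at the ladder radius nearest
R× rather than by re-gridding at the interpolated radius, since the
winding number is only defined on the ladder grids.

## Segmentation

Thresholding (Otsu by default; the threshold is a free choice since real
pipelines tune it per channel) → removal of connected components below 10
px → skeletonization to a 1-px network → branch points (≥3 skeleton
neighbours, 8-connectivity) merged by single linkage within 2 px into
vertices → enclosed faces of the skeleton complement (4-connectivity)
become cells, with each face's vertices ordered along its boundary contour
and joined by straight lines. Neighbours are faces sharing an edge between
two consecutive vertices, so an interior cell has exactly as many
neighbours as vertices. Rosettes (≥4 cells at a point) remain single
vertices. Faces below 32 px or with fewer than 3 vertices are dropped with
a logged warning. Faces with pixels within 6 px of the image edge are
flagged as border: when the field-of-view boundary itself carries signal,
clipped cells appear as ordinary enclosed faces and must still be excluded
from ensemble statistics. Pixel centres sit at ((col+0.5)·s, (row+0.5)·s)
with pixel size s; the pixel→μm conversion happens exactly once, when
polygons are built.

## Synthetic monolayers

The generator produces space-filling tilings (confluency: cell areas sum
to the box area to 10⁻⁶ relative) as Voronoi diagrams of a triangular
lattice with three disorder/anisotropy channels:

* **jitter** ∈ [0, 1]: i.i.d. displacement of each seed, uniform in a disk
  of radius jitter·spacing/2. Controls cell-shape irregularity.
* **warp** (rms radians): a smooth displacement field summing 12 transverse
  sinusoidal modes with log-spaced wavelengths between 2 R_cc and 6 R_cc,
  normalised so the local rotation ω = (∂_x u_y − ∂_y u_x)/2 has the given
  rms. Because a local rotation turns the p-fold phase by pω, six-fold
  coherence decays much faster with distance than two-fold coherence — the
  elastic-disorder mechanism that gives a crystal-like packing
  scale-dependent p-atic order. A jittered lattice alone keeps long-range
  six-fold order and would never cross over.
* **elongation** ≥ 1: the target major/minor cell aspect ratio, realised as
  an area-preserving stretch (√e, 1/√e) about a configurable axis. The
  stretch is applied to the *tiling* (Voronoi computed in isotropic space,
  polygons then mapped affinely): Voronoi diagrams do not commute with
  anisotropic maps, and tessellating stretched seeds flips the cell
  orientation to the perpendicular axis beyond e ≈ 1.7 in aspect terms.
  With the tiling-stretch, an unjittered lattice satisfies exactly
  |γ₂| = (e − 1/e)/(e + 1/e) with orientation equal to the stretch axis.

Lattice spacing equals the target R_cc (the unjittered lattice realises it
exactly; jittered fixtures stay within a few percent, verified over seeds).
Rendering rasterises cell edges as ridges of approximately the requested
line width (amplitude 1), applies an optional Gaussian blur (default σ = 1
px) and adds Gaussian noise; pixels follow the same centre convention as
segmentation, so a rendered monolayer re-segments onto itself. One integer
seed feeds three documented RNG streams (0: jitter, 1: image noise,
2: warp modes); identical configs are bit-identical.

**Study conditions.** The standard ensemble covers mean cell-cell distances
13.6, 16.2 and 21.4 μm (centres of three of the 2.6 μm density intervals
spanning the observed 9.7–28.5 μm range), base aspect ratios 1.1–1.4, five
seeds, ~200 cells per monolayer. Baseline disorder is fixed at jitter 0.22
and warp 0.40 rad, which makes the tiling statistics scale-free: in units
of the cell size, dense and sparse monolayers are statistically identical.
Density instead enters through cell shape, as in real epithelia where the
shape index rises with cell–cell distance: the study conditions add an
aspect-ratio increment that grows linearly with R_cc across the observed
span (up to +0.3) and fades out once the base aspect approaches 1.45,
where cells are already strongly elongated. These constants were fixed
once, while designing the generator, so that the synthetic ensembles
reproduce the qualitative structure of real monolayers — single cells
predominantly six-fold, hexatic order decaying within the analysed window,
crossover scales of order one to a few cell diameters that shrink with
elongation and with sparsity — and they are not revisited per analysis.

**What the generator does not emulate.** No mechanics (no force balance,
vertex-model energy, division or motility), no curved junctions (cells are
convex-ish polygons with straight edges), no intensity heterogeneity or
illumination gradients in the rendered images, and a noise model that is a
stand-in rather than a claim about any microscope. Passing tests therefore
demonstrate that the *analysis chain* is correct and that the expected
biological trends emerge under controlled statistics, not that real
microscopy data would yield these numbers.

## Density grouping and statistics

Monolayers are grouped by R_cc into contiguous half-open intervals of
width 2.6 μm labelled D1…Dk. The left edge of D1 defaults to the minimum
observed R_cc (the span, not the origin, is the documented quantity) and
is configurable. R_cc histograms use 0.2 μm bins. Two-group comparisons
use the two-sided Wilcoxon rank-sum test (scipy's Mann–Whitney U, exact
for small tie-free samples) with the conventional star labels (≤0.05 *,
<0.01 **, <0.001 ***, <0.0001 ****, ns otherwise). Multi-group testing
(Kruskal–Wallis, Dunn) is left to standard library calls.

## Numerical conventions

Coordinates are image-like (x right, y down, μm); polygon "counterclockwise"
means positive shoelace area in that frame. Degenerate inputs fail loudly:
coincident seed points name the offending indices, zero-area polygons and
empty images raise, all-missing ladder radii are dropped with a warning.
Problem sizes in tests (~200-cell monolayers, 5 seeds per condition,
10³-polygon property sweeps, 10⁶ Monte-Carlo samples for the honeycomb
packing fraction) were chosen as the smallest ensembles whose pass/fail
criteria are stable across reruns.

## Known limitations

* The straight-line polygon approximation discards junction curvature;
  segmented areas are biased low by the sagitta of each edge (<5% on the
  fixtures tested).
* Grid points near the field-of-view border average over truncated disks;
  profiles at the largest radii carry this bias.
* The crossover estimator interpolates linearly between ladder rungs; its
  resolution is limited by the R_cc/2 step, and in near-degenerate cases
  (profiles touching tangentially) the per-monolayer estimate is noisy —
  use the pooled estimator for ensemble statements.
* Segmentation assumes a closed junction network; gaps in the signal merge
  faces, and no machine-learning fallback is provided.
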