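# Methods

## Detection model and assumptions

The detector assumes the imaging regime of freshly transplanted paddies
photographed at nadir: seedlings 5–8 days after transplanting, upright, with
a consistent light-yellow colour that separates cleanly from dark wet soil
in RGB space. It is a fixed-rule pipeline, not a trained model, and its
constants are pixel-scale dependent (calibrated for ≈ 0.2 cm/px imagery):

| parameter | default | meaning |
|---|---|---|
| `rg_threshold` | 220 | foreground iff (R+G)/2 strictly above this |
| `b_threshold` | 200 | and B strictly below this (rejects water bubbles) |
| `min_denoise_major_axis` | 3 px | components with smaller second-moment major axis are noise |
| `dilation_radius` | 11 px | disk dilation merging one hill's shoots |
| `split_quantile` | 0.85 | area percentile separating single hills from candidate merges |
| `erosion_radius` | 5 px | disk erosion splitting merged hills |
| `refine_min_area` | 400 px | eroded fragment kept iff area strictly above |
| `refine_min_major_axis` | 40 px | and major axis strictly above |
| `connectivity` | 8 | pixel adjacency for both labelling passes |

Inequalities are strict exactly as listed. The discrete disk of radius r
contains offset (dr, dc) iff dr² + dc² ≤ r²; morphology results are
bit-exact functions of that definition. The area quantile uses the
linear-interpolation estimator; with few components per image the estimator
choice is visible, so it is fixed and documented. Coordinates are (row, col),
0-based, pixel centres at integers; centroids are unweighted means of member
pixels. Components touching the image border are retained and flagged.

The quantile split sends the *largest* 15 % of dilated components through
erosion refinement: dilation is what fuses adjacent hills, so the oversized
components are precisely the ones that may contain several hills. Components
at or below the percentile are accepted directly.

## Tessellation

Cluster positions are triangulated (Delaunay, via Qhull; the triangulation
is unique up to co-circular ties, so the construction algorithm is
immaterial) and each site's occupied region is assembled from the
circumcenters of its incident triangles, sorted clockwise around the site.
Coincident circumcenters — exact lattices put four sites on one circle — are
merged within 1e-9 of the point-cloud scale before ring construction;
without the merge the ring would degenerate. Cell area is the absolute
shoelace sum, so the ordering convention is cosmetic.

Hull sites have open cells (`bounded=False`, no area). Among bounded cells,
only those wholly contained in the convex hull of the sites are marked
`interior` and used in area statistics. This minus-sampling edge correction
matters: the bounded cell of a site just inside the hull legitimately
extends far beyond the planted region (no neighbours exist to close it off),
and such edge cells would dominate the CV with window artefacts — a random
layout would report CV ≈ 7 instead of the Poisson–Voronoi value ≈ 0.53. For
a perfect lattice the correction changes nothing: all 13×13 inner cells of a
15×15 grid are interior and the index is exactly 0. The sensitivity of CV to
this boundary treatment is the main free choice of the method; both
`bounded_areas()` and `interior_areas()` are exposed so users can compare.

The index is scale-invariant (CV of c·x equals CV of x), so tessellating in
pixels or centimetres gives identical uniformity values; units are carried
as metadata only.

## Indices and scores

σ uses the population divisor n (root mean squared deviation), consistent
with CV's dimensionless definition. `uniformity_index` returns a
distinguished `PERFECTLY_UNIFORM` sentinel at CV = 0 rather than infinity,
so downstream code must handle the lattice case explicitly.

The accuracy score is deliberately nonstandard — (TP+FN)/(TP+FP+TN+FN) with
TN = 0 by convention — because that is how the reference score table it is
validated against is defined; precision, recall and F1 are standard.
Position matching is greedy globally-nearest one-to-one under a distance
gate (default: roughly half the nominal plant spacing), with ties broken by
lowest index; this replaces the manual matching a field study would do.
Location errors are Euclidean pixel distances × gsd, summarised by a
maximum-likelihood gamma fit with location fixed at zero (two free
parameters; the model mean is shape × scale). Zero-variance samples are
rejected as degenerate rather than fitted.

## Simulators

All generators are pure functions of (spec, seed), with NumPy's PCG64.

* **Lattice** — x(i,j) = PD·i, y(i,j) = RD·j; defaults rows = cols = 15,
  PD = 3, RD = 2 (row:plant spacing 2:3), the canonical simulated plot.
* **Perturbation** — independent Gaussian offsets per axis, written as
  σ·z so that σ = 0 reproduces the lattice bit-for-bit. σ grids are
  fractions of PD/RD (0, 0.1, …, 1.0) by default; absolute units are
  available via `fractional=False`.
* **Omission** — the boundary ring is always retained (keeping the
  tessellation window stable) and each interior cluster is dropped i.i.d.
  with probability P, realised as u < P on per-cluster uniforms so that
  omitted sets are nested in P under a shared seed.
* **Random field** — n i.i.d. uniform points in the lattice's bounding
  rectangle; default n = 225 to match the lattice scenarios.

`run_cv_experiment` sweeps a grid with common random numbers: one derived
sub-seed per replicate, reused at every level, so level-to-level CV
differences are paired and trend tests need far fewer replicates. Levels
whose layout has fewer than 4 points or no interior cell are flagged in the
output, never silently dropped. Default problem sizes used by the test
suite: 11 σ-levels × 24 replicates, 50 omission levels × 16 replicates, and
200 random-field replicates — enough for the paired 2-SE trend assertions
to be stable while keeping the suite fast.

## Synthetic scenes

The renderer emulates only what the detector keys on: colour separability
and blob geometry. Blades are 3-px-wide line segments radiating from each
hill position at evenly spaced, jittered angles; soil, blade and bubble
colours are drawn from ranges constructed so blades always satisfy the
colour rule, soil always fails its first clause and bubbles (B ≥ 200) its
second; speckle noise adds isolated foreground-coloured pixels that the
major-axis-< 3 denoise step must remove. Default gsd is 0.2 cm/px and
default hill spacing 30 × 20 cm (150 × 100 px), far above the
dilation-merge distance, with blade length 18 px so that eroded fragments
of any quantile-split component still pass the 400 px / 40 px filters.

What passing on these scenes shows: the pipeline's logic (colour rule,
denoise, merge/split, centroid accuracy) is correct under its own stated
imaging assumptions. What it does not show: robustness to real-field
variation — growth-stage colour drift, shadows, water reflectance,
perspective, algae — none of which is modelled; the renderer is schematic by
design.

## Numerical notes and limitations

* Circumcenters of near-degenerate (sliver) triangles are computed in
  double precision from the 2×2 closed form; their large magnitudes are
  legitimate Voronoi vertices and are handled by the hull-containment
  filter rather than by clipping.
* Exactly collinear point sets and point sets with duplicates are rejected
  with specific errors; the CLI deduplicates CSV input with a warning.
* The "space sharing" property — the shared boundary of two adjacent cells
  passing through the midpoint of their sites — holds as stated only for
  Gabriel edges; in general the midpoint lies on the supporting bisector
  line of the shared edge. Tests check the general line property on random
  sets and exact midpoint containment on lattices.
* No bounded-window (clipped) Voronoi is implemented: field-boundary
  clipping, weighted tessellations and alternative uniformity statistics
  (nearest-neighbour indices, Ripley's K) are out of scope.
* The detector is not expected to transfer beyond the light-yellow
  seedling stage or to other sensors without re-calibrating the colour
  thresholds and pixel-scale constants.
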