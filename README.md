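# ricegrid

Estimating and evaluating how evenly transplanted rice clusters (hills) are
laid out in a paddy field, from nadir RGB imagery such as low-altitude UAV
photos.

Stand uniformity matters agronomically: uneven hill spacing degrades canopy
light distribution, ventilation and fertiliser efficiency, and it is the
quantity by which mechanical transplanters and seedling-throwing practice
are compared. `ricegrid` implements a complete measurement chain for it:

1. **Cluster detection.** A few days after transplanting, seedlings are
   light-yellow and upright on dark wet soil. A pixel is foreground iff

   `(R + G)/2 > 220 and B < 200`

   (the blue clause rejects bright water bubbles). Small components (second-
   moment major axis < 3 px) are discarded as noise; a disk dilation
   (radius 11 px) merges each hill's shoots into one blob; blobs at or below
   the 85th area percentile yield centroids directly, while larger blobs
   (candidate merged hills) are eroded (disk, radius 5 px), relabelled, and
   fragments with area > 400 px and major axis > 40 px yield centroids.
2. **Occupied-area assignment.** Cluster positions become the sites of a
   Delaunay triangulation; each site's occupied region is its Voronoi cell,
   built explicitly as the angularly ordered ring of circumcenters of the
   incident Delaunay triangles, and its area by the shoelace formula.
3. **Uniformity index.** With cell areas x_1..x_n, the heterogeneity index
   is the coefficient of variation

   `CV = σ/x̄,  σ = sqrt(Σ(x_i − x̄)²/n)`

   (population divisor). CV = 0 for a perfect planting lattice and ≈ 0.5
   for a completely random layout; the uniformity index is 1/CV.
4. **Validation by simulation.** Seeded generators produce perturbed
   lattices (Gaussian positional noise per axis), lattices with interior
   omissions (boundary ring preserved), and fully random layouts, and sweep
   CV against the noise level or omission probability.

Because no field imagery is distributed with the package, a synthetic scene
renderer draws blade tufts / soil / bubble noise with exact ground truth, so
the whole chain is testable end to end.

## Worked example

Render a synthetic 3×3-hill scene, detect the hills, score the detection
against ground truth, and compute the uniformity of a simulated field:

```sh
$ ricegrid render --rows 3 --cols 3 --seed 7 --out-image scene.png --out-truth truth.csv
rendered 9 clusters (422x322 px) -> scene.png

$ ricegrid detect scene.png --gsd 0.2 --out points.csv
detected 9 clusters -> points.csv

$ ricegrid evaluate points.csv truth.csv --gsd 0.2 --match-radius 25 --out eval.json
{"precision": 1.0, "accuracy": 1.0, "recall": 1.0, "f1": 1.0}

$ ricegrid simulate --mode perturb --sigma1 0.3 --sigma2 0.3 --seed 1 --out perturbed.csv
225 points -> perturbed.csv

$ ricegrid uniformity perturbed.csv --out report.json
{"n": 225, "n_interior": 169, "mean": 6.000402893429478, "sigma": 1.4224357300195152,
 "cv": 0.23705670357187206, "uniformity": 4.218400006970547, "perfectly_uniform": false}
```

All nine rendered hills are recovered exactly (precision = recall = 1). The
perturbed 15×15 lattice (plant spacing 3, row spacing 2, Gaussian noise with
σ = 0.3 of the spacing on each axis) has 169 interior Voronoi cells with
mean area ≈ 6.0 (= PD×RD) and CV ≈ 0.237 — a stand noticeably less uniform
than a perfect lattice (CV = 0) but far from fully random (CV ≈ 0.5). An
unperturbed lattice (`--sigma1 0 --sigma2 0`) reports `"cv": 0.0` with
`"perfectly_uniform": true`.

Other subcommands: `tessellate` (cell areas + GeoJSON), `simulate --levels`
(CV parameter sweeps), `repro-figures` (CV histogram of random layouts and
the CV-vs-σ / CV-vs-P trend curves). Every command accepts `--config
config.yaml` and writes its resolved configuration next to its outputs.

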