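# Methods

This note documents the models and procedures implemented in `canopyseg`,
the choices made where the method description leaves room, and what the
synthetic test scenes do and do not establish.

## Crown delineation

The delineation assumes that, within a vegetated canopy, a tree apex is a
local maximum of near-infrared brightness and that brightness decays
toward the crown edge. It operates on a single band of the hyperspectral
cube — the band whose center wavelength is nearest 810 nm, where healthy
canopies are bright and atmospheric water absorption is weak. Nearest-band
lookup breaks ties toward the lower wavelength so results are
deterministic on evenly gridded sensors.

**Vegetation mask.** NDVI = (NIR − RED)/(NIR + RED) with configurable
band wavelengths (defaults 680 and 800 nm; the exact pair is not critical
on a vegetated/non-vegetated contrast of this size). Only pixels with
NDVI *strictly below* the threshold (default 0.6) are masked, so a pixel
exactly at the threshold is kept. Pixels with invalid data or a zero
denominator are masked. An all-masked scene is a warning, not an error:
an empty crown set is a legitimate result on non-forest imagery.

**Seed detection.** A pixel is a seed iff it is unmasked and equals the
maximum of the `window_px × window_px` window centered on it (default
3 × 3 — small windows favor the small crowns that dominate open
woodland). The window is clipped at image edges, not padded, and masked
pixels are excluded from the maximum. On a plateau every member ties the
maximum and every member becomes a seed; this literal reading is kept
because plateaus have measure zero on radiometric data and a documented
rule beats a hidden heuristic.

**Region growing.** Starting from the label map with `L = k` at seed k,
regions grow over 4-connected neighbors. An unlabeled, unmasked neighbor
joins region *n* iff its center lies strictly within `dist_max` pixels of
seed *n*'s center (Euclidean, pixel units — at 1 m resolution the default
`dist_max = 4` means 4 m) and its value strictly exceeds
`perc_thresh · s_n` (default 0.4). Both comparisons are strict as the
conditions are stated; in particular `dist_max = 1` freezes every region
at its seed. Only unlabeled pixels can be claimed — a labeled pixel is
never re-assigned. Growth sweeps are level-synchronous: every region
expands by at most one ring per sweep, and a pixel proposed by several
regions within a sweep goes to the region with the nearest seed, ties to
the lower seed id. This tie-break is our own; it makes the output
deterministic and independent of seed enumeration order, which the
naive "first region to arrive wins" rule is not. Because both growth
conditions are static per region, a pixel rejected once by a region can
never satisfy it later, so the frontier-based implementation visits each
candidate pixel at most once per adjacent region; the test suite checks
it against an independent full-grid sweep oracle.

**Polygonization.** Each region's member-pixel *centers* (pixel (0, 0)
maps to the center of its cell) are wrapped in a 2-D convex hull.
Degenerate regions — fewer than three centers, or collinear ones — would
give zero-area hulls that break area accounting, so they instead emit the
dissolved union of their pixels' 1-pixel footprint squares. A convex hull
cannot represent concave crown outlines; this is an accepted limitation
of the method, visible as slightly optimistic crown footprints.

**Parameter tuning.** `tune_parameters` delineates with every candidate
in a user-supplied grid and keeps the candidate with the highest
two-level Jaccard score (below); ties go to the earliest candidate in
grid order.

## Delineation scoring

For each reference crown, the Jaccard index is computed against every
overlapping predicted crown and only the best is kept (a predicted crown
may be the best match of several references; exclusive one-to-one
assignment is deliberately not imposed, as the scoring is defined from
the reference side). The plot score is the mean over the plot's reference
crowns and the dataset score the mean over plot scores — the two-level
mean weights plots equally regardless of how many crowns they contain,
and differs from the flat mean whenever plots differ in size.

The area-based overall confusion matrix dissolves reference and predicted
polygons before intersecting, so overlapping crowns are never counted
twice: `ref_covered = |R ∩ P|`, `ref_missed = |R| − ref_covered`,
`pred_excess = |P| − ref_covered`. The challenge's bar-chart names for
these cells (TruePositive, FalsePositive, FalseNegative) are non-standard
— its "FalseNegative" is predicted excess area — so the implementation
stores neutral names and exposes the challenge labels only in report
output. For the per-plot breakdown, each predicted crown is attributed to
the plot whose reference crowns it overlaps most; predicted crowns
touching no reference are reported under plot `None`. Intersection areas
below 1e-9 m² are treated as zero.

## Alignment

Allometric gap filling uses power laws fitted by nonlinear least squares:
field crown radius from height × stem diameter, `R = a·(H·D)^b`, and
crown height from crown radius, `H = a·R^b`. The optimizer starts from
the log–log ordinary-least-squares solution, stops at a relative SSE
tolerance of 1e-10 or 200 iterations, and falls back to the log–log
estimate (flagged `converged=False`) if it fails. Stem diameter stays in
cm as recorded, so the `H·D` regressor is in m·cm; the coefficient `a`
absorbs the units and no conversion is applied. Measured values are never
overwritten by imputations.

Where the description leaves the geometry open we chose: crown position
is the polygon centroid; crown radius is the equal-area circle radius
`r = sqrt(area/π)`; crown height, when not supplied, is the maximum CHM
value over pixel centers inside the polygon (maximum, not mean, to match
tree-height semantics); when a field record carries two radii (maximum
and perpendicular), their mean is used.

The combined distance is `D = D_pos + D_attr` with
`D_attr = sqrt((ΔH)² + (ΔR)²)` — meters of height and meters of radius
summed without weighting, exactly as defined. The default matching mode
is "nearest": each crown takes its argmin-D tree, and a tree may be
claimed more than once. Because duplicate claims are a known failure mode,
a "one-to-one" mode accepts pairs greedily in ascending D with each crown
and tree used once; ties in D break by input order, and the result is
invariant to row reordering. An optional `max_distance` cut-off exists
but is off by default, since the method itself imposes none. The manual
GIS review step that would follow matching is out of scope; the CLI
exports a line layer connecting matched pairs to support it externally.

## Species classification

Each crown pixel's spectrum is divided by its band sum before anything
else, removing brightness differences between flight lines while keeping
spectral shape; all-zero rows are dropped with a warning. Band selection
then runs SFFS with the Jeffries–Matusita criterion on the *normalized*
training pixels: classes are modeled as Gaussians (mean and covariance
per class, ridge 1e-6 on the covariance diagonal for invertibility;
classes with fewer than two pixels are excluded with a warning), and the
subset criterion is the mean of pairwise JM distances over class pairs
(the minimum-pairwise criterion is available via config). SFFS adds the
band that maximizes the criterion, then conditionally removes bands while
removal beats the best criterion already recorded at the smaller size;
the best subset at every size is retained so users can pick any
cardinality after the fact. The default `max_features` is 40 — on our
50-band synthetic scenes this spans most of the spectrum, and the
best-at-size trace is the intended tool for choosing a smaller set.

The classifier is a multiclass RBF SVM on z-scored features (training
statistics), with C ∈ {1, 10, 100} and γ ∈ {0.1, 1, 10}/d chosen by
5-fold cross-validation (stratified when every class allows it, plain
k-fold with a warning otherwise; fixed seed 1234 by default). Each
pixel's feature vector is the selected bands plus one CHM value per
crown — the maximum CHM inside the crown polygon, replicated onto the
crown's pixels. Pixel labels are aggregated per crown by majority vote;
ties go to the class with more training pixels, then alphabetically.

Confusion matrices are stored with rows = predicted and columns =
reference. Producer's accuracy is the column-wise recall, user's the
row-wise precision, mean class accuracy the unweighted mean of producer's
accuracies over classes with a nonzero column total, and kappa the
chance-corrected agreement from the marginals. Metrics are reported in
percent and rounded to one decimal in report output. On the published
challenge matrix the implementation reproduces every printed cell except
one user's accuracy printed as 91.4 where the printed counts give
21/23 = 91.3; the computed value is reported.

## Synthetic scenes

`make_scene` generates a 1 m-resolution scene (default 100 × 120 px, 25
crowns) that reproduces the statistical structure the pipeline assumes:
circular-to-elliptical crowns placed by rejection sampling with center
spacing above the sum of radii; per-pixel spectra drawn from per-species
multivariate normals and multiplied by a radial brightness profile
(linear decay, 60% apex-to-edge) so the NIR maximum of every crown is its
apex pixel — asserted at generation; background with NDVI far below the
0.6 threshold and crowns far above it (the profile cancels in the NDVI
ratio); a CHM cone reaching the true height at the apex
(`H = 8·R^0.9`, giving ≈ 23 m mean canopy height at mid-range radii); and
a stem table at the apices with 0.5 m Gaussian jitter, diameters obtained
by inverting `R = 0.5·(H·D)^0.4`, and the measured radius present for 70%
of stems. Species mean spectra sit at the vertices of a regular simplex
in spectral space, scaled so every pair realizes the same target JM
(default 1.9) under the shared diagonal covariance (sd 0.005 reflectance
per band); the perturbed bands lie in 480–660 nm, clear of the NDVI
bands. The 50-band 400–1000 nm grid keeps exhaustive band-subset oracles
tractable.

What the generator does *not* emulate: overlapping or interlocking
crowns (a separate overlap mode exercises only the contention tie-break),
shadows, understory vegetation, sensor striping and atmospheric
artifacts, within-crown spectral gradients beyond the radial brightness
profile, and species spectra that differ in covariance rather than mean.
Passing end-to-end tests on these scenes therefore demonstrates
correctness of the algorithms under their own assumptions — not expected
accuracy on real imagery, where crown adjacency and radiometric artifacts
dominate the error budget. Problem sizes in the test-suite and the
acceptance script (25-crown scenes, 20 × 20 oracle grids, 6-band SFFS
oracles) were chosen so every brute-force oracle remains exhaustive.

## Numerical choices

- Geometry areas below 1e-9 m² are zero; Jaccard of two empty polygons
  is 0 by convention.
- Rasters are treated as generic intensity (radiance or reflectance);
  nothing depends on the physical unit.
- Layers with explicitly different CRS identifiers are rejected, never
  silently reprojected; unknown (None) CRS is not compared.
- Region-growing distance is measured between pixel centers in pixel
  units; map-unit distances follow from the pixel size.
- Power-law fitting requires strictly positive x and y; a constant y
  fits as `b = 0`.

## Known limitations

- Convex hulls overestimate concave crowns and cannot represent holes.
- The delineation finds only sunlit, locally-maximal crowns; understory
  and suppressed trees are invisible to it by construction.
- Greedy one-to-one matching is order-optimal, not globally optimal; a
  Hungarian assignment would minimize total distance but would no longer
  match the stated greedy rule.
- The SVM defaults target hundreds-to-thousands of training pixels;
  heavily imbalanced species sets will bias toward dominant classes, and
  no resampling or cost-sensitive remedy is included.
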