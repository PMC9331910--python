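# Methods

`bunchmetric` measures a table-grape bunch from multi-view depth-camera
point clouds: it extracts the bunch from the raw scene, registers twelve
turntable views into one complete model, reads off length/width/height in
the bunch's own coordinate frame, and estimates volume with five
reconstruction methods. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic validation does and
does not demonstrate.

## The measurement problem

A bunch is an irregular aggregate of near-spherical berries. Its volume is
the volume of the union of the berries — crevices between berries are not
part of it, but neither are they visible to any single envelope model. The
five estimators bracket this quantity in characteristic ways:

* **GM (geometric model)** — a bounding cylinder: the larger of length and
  width is the diameter, the height is the cylinder height,
  `V = pi r^2 h`. Grossly biased high (it swallows every crevice and the
  box corners), but trivially robust.
* **CH (convex hull)** — quickhull over the model; still biased high by
  every concavity, but tight against the silhouette.
* **AS (alpha-shape)** — the sub-complex of the Delaunay tetrahedralization
  whose circumsphere radius is at most alpha. Interpolates between the
  point set (small alpha) and the hull (large alpha); alpha is a length in
  cm here, and a useful default is ~1.25 times the typical berry radius,
  large enough to close berry-to-berry gaps without filling crevices.
* **VB (voxel occupancy)** — occupied-cell count times cell volume. On a
  surface-only cloud this measures the sampled *shell*, not the enclosed
  solid; the default edge is 0.2 cm so the number reported is transparent
  rather than accidentally inflated by huge cells.
* **PB (Poisson reconstruction)** — recovers a smoothed indicator function
  from oriented surface samples, extracts its isosurface, and integrates
  the enclosed volume exactly from the watertight mesh. This is the
  method of record; the others are comparators.

Volumes of watertight triangle meshes (used by CH, AS and PB) are computed
by the signed-tetrahedron sum `V = |sum (1/6)(v1 x v2) . v3|` over faces;
the signed sum telescopes for any closed, consistently wound surface, so
the result is independent of the coordinate origin. The absolute value
makes a globally reversed winding harmless; an open mesh is an error, not
a number.

## Units and sizes

All coordinates are centimetres; volumes cm^3. Sizes are measured in the
bunch's PCA frame: the axis of largest variance is treated as the rachis
direction and carries the height h (bunches are elongated vertically);
the remaining two principal extents are length l and width w with l >= w.
A `frame="lab"` option measures along world axes instead for non-elongated
objects.

## Poisson reconstruction details

The indicator gradient equals the (smoothed) oriented surface measure, so
chi solves the Poisson equation `laplacian(chi) = div V` where V is the
Gaussian-splatted normal field. The discretization is a regular node grid
over the bounding box padded by `max(4 sigma, 6 cells)`:

1. each oriented sample's normal is binned to its nearest node and the
   field is smoothed with a separable Gaussian (`gaussian_width`, default
   1.5x the mean nearest-neighbor spacing);
2. divergence by central differences;
3. the 7-point-Laplacian system with zero-Dirichlet boundary is solved
   exactly by a type-I discrete sine transform — the spectral
   factorization of that same sparse system, O(n log n) with no fill-in,
   entirely adequate below 256 cells per axis on a desk-scale object;
4. the isovalue is the mean interpolated indicator value at the input
   samples (plus an optional `iso_offset`);
5. marching cubes extracts the isosurface, the largest connected component
   is kept, and the result is audited edge-by-edge for watertightness —
   a leaky extraction raises instead of returning a wrong volume.

Inputs whose normals point predominantly inward (negative mean dot with
the centroid-to-point direction) are flipped to the outward convention;
orientation only changes the sign of the indicator, never |volume|.
`grid_resolution` (cells along the longest axis, default 128) is the main
accuracy/time dial: a dense r = 5 cm sphere reconstructs to ~0.05% of the
analytic volume, and the battery in the test suite holds PB and CH within
5% of analytic on such solids.

## Segmentation

A raw view contains the bunch, a positioning plate behind it, and sparse
outliers. Cropping by coordinate ranges removes the bulk of the scene
(crop thresholds are inherently scene-specific and stay user input), then
curvature-seeded region growing splits the rest into smooth connected
clusters and keeps the largest. Curvature is the surface variation
`lambda_min / (l1+l2+l3)` of the k-nearest-neighbor covariance (0 on a
plane, at most 1/3); normals come from the same eigendecomposition,
oriented toward the camera, and the growth test uses the *unoriented*
angle because normals perpendicular to the camera axis have an arbitrary
sign.

Defaults (k = 30, angle 60 degrees, curvature threshold 0.3, minimum
cluster 400) were chosen on generator-labelled scenes. They are looser
than textbook values for a reason worth recording: at 2 mm sensor noise on
~1.5 cm berries, the measured surface variation on the bunch itself is
0.08–0.18, so a small curvature threshold stops seed propagation and
shatters the bunch into per-berry fragments. What actually separates the
bunch from the plate is spatial disconnection — the kNN graph never
bridges the ~6 cm gap — so the angle/curvature thresholds can be generous.
On labelled scenes (background plate + 1% outliers, five seeds) this
yields precision and recall above 0.99.

## Registration

The merge is hierarchical: the twelve views form four triples, each outer
view registered to the triple's middle view; the four quarter-models then
merge sequentially; finally each view is re-registered to the union of the
other eleven (two passes). No loop-closure distribution is applied: the
scheme remains sequential, and residual ring drift is visible in the logs
rather than silently redistributed.

Coarse alignment maps the source PCA frame onto the target's. For partial
turntable views this is genuinely ambiguous: the visible hemisphere always
faces the camera, biasing every view's frame the same way, and the
axis-sign choice cannot be trusted from a small subsample. Pairwise
registration therefore screens the full ambiguity class — all four
right-handed sign combinations, swept in yaw about the dominant axis —
with a short ICP pull-in per candidate, ranks candidates by a truncated
nearest-neighbor cost (comparable across poses, unlike each run's inlier
RMSE), and refines the best few at the configured then a halved
correspondence cutoff. Quarter merges are initialized from a direct
registration of the boundary view pair, which is unambiguous where
whole-quarter matching is not.

The ICP update is configurable. The default `icp()` is classical
point-to-point: nearest-neighbor correspondences inside a hard cutoff and
the closed-form SVD rigid update (reflection-guarded). The merge pipeline
enables three matching refinements that experiments on synthetic scans
showed to be decisive at 2 mm noise:

* **point-to-plane, symmetric** — residuals along the averaged
  source+target normal. Plain point-to-point locks into berry-scale false
  minima a few degrees from truth (its basin of attraction is narrower
  than any realistic initialization); one-sided point-to-plane frees the
  tangential sliding but leaves a curvature-induced drift. The symmetric
  form has both the wide basin and no sliding bias.
* **reciprocal correspondences** — a pair is kept only if each point is
  the other's nearest neighbor, suppressing the pull of surface seen in
  only one view.
* **normal gating and trimming** — matches whose normals disagree by more
  than 25 degrees are rejected and only the closest 85% of pairs enter the
  solve. This targets a specific failure mode: adjacent views see
  30-degree-offset caps of each berry, and unglated matching pulls the
  caps together tangentially; around the ring those per-pair pulls compose
  into a coherent radial inflation of the whole model (~+6% volume).

With all three, twelve views at 2 mm noise merge with every adjacent
relative pose within ~1.7 degrees / 0.10 cm of ground truth and a Poisson
volume within ~2.4% of the same pipeline run at ground-truth poses.

Voxel-grid downsampling (cell centroids, normals re-averaged) and moving-
least-squares smoothing finish the model. MLS fits a local plane per point
with Gaussian weights `exp(-d^2/h^2)` over neighbors within `radius`
(default 1.2 / 0.6 cm), iterates the fit twice with weights recentred on
the projection, and projects the point; points with fewer than four
neighbors pass through flagged. This collapses the doubled "ghost"
surfaces of imperfect registration: two sheets 0.3 cm apart reduce to a
single mid-surface with more than 4x less thickness, and no point ever
moves farther than the neighborhood radius.

## The synthetic scanner (what it emulates, what it does not)

The generator is the package's only ground truth. A bunch is a connected
packing of spherical berries (default 60 berries, radius 1.5 +- 0.12 cm
truncated at 3 sd, height 14 cm, interpenetration capped at a quarter of
the summed radii) placed on rings around a vertical rachis, inner rings
first so any berry count spans the full height. Two realism choices are
deliberate and load-bearing for registration: the packing is stretched to
an elliptical cross-section (aspect 1.6), and ring phases are drawn at
random — a body of revolution or a periodic berry lattice would hand PCA
alignment and ICP ambiguities that no real bunch exhibits.

Scanning mimics the turntable protocol: 12 views, the bunch rotated 30
degrees about the vertical axis between views, a camera 1 m away on +Z,
hidden points removed by exact sphere/segment occlusion, isotropic
Gaussian noise of 0.2 cm (the sensor's 2 mm accuracy), and optionally a
positioning plate 6 cm behind the bunch plus 1% uniform outliers, all
labelled per point. The true volume is a Monte-Carlo union-of-spheres
integral with a binomial standard error — the in-silico counterpart of the
water-displacement measurement, and the reference for every accuracy
claim.

What passing these tests does *not* show about real data: berries are
perfect spheres with analytic normals and no color; sensor noise is
isotropic and homoscedastic rather than depth-dependent; the plate is the
only clutter; and the scanned "complete" model genuinely includes
interior-facing surfaces wherever they are line-of-sight visible, whereas
a real camera sees almost nothing of the bunch interior. That last
difference flips the sign of the Poisson bias: on oracle-sampled complete
models PB runs ~1–2% *low* (smoothing trims convex caps), while on real
scans — and in the packaged reference table — closed-over interior voids
push PB slightly *high*.

## Evaluation and the packaged reference table

Agreement metrics are the error `E = y - yhat`, RMSE, and two R^2
conventions: `r2_identity` scores estimates against the identity line
(1 - SS_res/SS_tot, unclamped, negative for biased estimators) and
`r2_linear_fit` is the squared Pearson correlation of the least-squares
regression of estimate on truth. Both exist because they answer different
questions — absolute agreement versus linear association — and only the
regression convention can reproduce the published per-method values given
the estimators' systematic biases (an estimator 57 cm^3 above truth on
average cannot score 0.99 against the identity line).

The packaged 16-sample reference table (size errors, water-displacement
truth, five estimator volumes) is checksummed, and `summarize_table1`
recomputes every derivable summary: column means and extrema, mean
excesses over truth, and per-method regression R^2. Three printed summary
cells are internally inconsistent with the rows they summarize — the
height-error max/min/mean triple is scrambled and the VB mean is 0.10
cm^3 off its column's arithmetic mean — and the reproduction report lists
them as discrepancies instead of matching them.

## Problem sizes and determinism

Default problem sizes (6,000 requested points per view of which ~3,000
survive visibility, 128-cell Poisson grids, 3–4 x 10^5 Monte-Carlo
samples) keep a full synthetic pipeline run around a minute on one core
while leaving every acceptance margin measured rather than assumed. All
randomness flows from one integer seed through named, spawned generator
streams per stage, so any stage's output is reproducible in isolation;
reruns with the same seed and configuration are byte-identical.

## Known limitations

* Ellipsoidal berries, stems/rachis geometry, color and photorealism are
  out of scope; the occlusion model is exact sphere-ray intersection, not
  a sensor simulation.
* Sequential merging leaves the 360-degree closure drift uncorrected
  (logged only); there is no pose-graph optimization.
* Alpha-shape surfaces on degenerate inputs (e.g. exact sphere samples,
  where every circumsphere is the sphere itself) are all-or-nothing in
  alpha; the volume is computed from the kept tetrahedra, which remains
  well-defined.
* MLS projects without resampling, so strongly non-uniform density
  survives smoothing.
* The CLI exposes crop ranges, alpha, voxel edge and grid resolution
  because no universal defaults exist for real scenes; the defaults here
  are calibrated to the synthetic study conditions.
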