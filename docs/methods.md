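# Methods

## The measurement model

A total ankle replacement (TAR) has two radio-opaque components — a tibial
tray and a talar dome — whose post-operative position is normally assessed
on a pair of weight-bearing radiographs: one anteroposterior (AP), one
lateral, acquired perpendicular to each other. `tarpose` treats each
component as a rigid 3D body with six pose parameters

* rotations `rx, ry, rz` (degrees) about the anatomical axes
  (`x` superior/longitudinal, `y` anterior, `z` lateral→medial), composed
  extrinsically as `R = Rz·Ry·Rx`;
* translations `tx, ty, tz` (mm).

Both radiographs are modelled as **orthographic** projections along `-y`
(AP) and `-z` (lateral). Clinical beams diverge, but the contour-overlay
principle uses no magnification model, so parallel projection with a
calibrated pixel spacing is the faithful formalisation; this is a stated
approximation, not an oversight. Both image planes share the longitudinal
`x` axis as their row axis: a single pose must therefore explain the
component outline in the two views *simultaneously*, which is what makes
the full 3D pose — including axial rotation, invisible on any single
radiograph — recoverable from plain films.

Alignment is reported against the anatomical tibial axis: coronal
(varus/valgus) and sagittal (anterior/posterior tilt) angles of each
component as seen in the AP and lateral view, axial rotation read from the
pose, and four inter-component contour-centroid distances (medial-lateral
and anterior-posterior offsets, plus the longitudinal separation as read
in each view). Signs: the positive coronal direction corresponds to `+ry`
(plateau's medial edge superior), positive sagittal to posterior tilt
(`-rz`), positive axial to right-handed rotation about `+x`; distances are
talar-relative-to-tibial with medial, anterior and distal positive. Only
magnitudes are clinically conventional, so the signs are fixed here and
recorded with every measurement. Tilting the reference axis by `θ` in a
view shifts that view's angle by exactly `-θ`.

## Silhouette projection

Two interchangeable silhouette paths exist:

* **exact** — the union of the projected triangles (front-facing only for
  a closed, consistently oriented mesh, which provably covers the
  silhouette and halves the work) as a `shapely` polygon. The boundary
  varies continuously with the pose, enabling sub-degree refinement.
  Unioning edge-sharing triangles leaves zero-width sliver rings that
  appear and disappear with pose; any ring below 0.05 mm² is discarded —
  they carry no geometry but inject noise into boundary sampling.
* **raster** — rasterise the triangles into a binary occupancy mask at the
  rig resolution and trace sub-pixel boundaries with marching squares;
  this is the route image-derived masks take, and it agrees with the exact
  path to within one pixel.

The quarter-pixel RMS tracing error of the raster path at the default rig
(0.5 mm/px, 512×512) is what we call the **raster tolerance**, 0.125 mm;
it was measured as the mean contour-cost between exact silhouettes and
their rasterised traces (≈0.12 mm) and is the scale against which cost
gaps are judged.

## Registration

The match between model and target outlines is a symmetric chamfer
distance for contour targets: contours resampled at ≤0.5 mm arc length,
mean bidirectional nearest-neighbour distance, averaged over the two
views (mm). Against a detected *edge map* the cost is the edges→model
mean (truncated at 6 mm): that direction measures point-to-curve
distances, whereas model→edge-pixel distances carry the tangential
spacing of the Canny chains, which varies with contour orientation and
was measured to bias rotations by more than a degree.

Pose optimisation treats the match as a **nonlinear least-squares**
problem: the per-point *signed* distances (negative inside the target
region) form the residual vector, solved by a trust-region reflective
method with finite-difference Jacobians. Two details matter and were the
difference between failure and machine-precision recovery:

1. Residuals must be signed. Unsigned distances have a V-shaped kink
   exactly at the optimum, which poisons finite differences (and defeated
   both a Nelder–Mead simplex and Powell's method in the narrow curved
   valley of the weakly observable axial rotation).
2. The silhouette geometry must be sliver-free (above), otherwise the cost
   itself is noisy at the 0.1 mm level.

Globalisation: the raw initial guess and a centroid-seeded variant
(translations shifted in closed form so the silhouette centroids match;
the AP view observes `tz` and `tx`, the lateral `ty` and `tx`) both serve
as first-class starts — centroid matching helps when the component sits
far from the guess, but under a large rotation offset it can lock a
wrong-overlap basin that the raw start avoids; further multi-start
perturbations (±5°/±5 mm, seeded) cover remaining rotation basins; and a
1D scan along the *least-observable direction* — the smallest right
singular vector of the residual Jacobian at the optimum, typically a
rotation near the component's stem axis — hunts the near-mirror competing
minimum of almost-symmetric components. Against edge maps the
refinement runs in two stages — a wide 6 mm truncation for pull-in, then
an inlier-only polish at 1.5 mm that rejects spurious noise edges — under
a soft-L1 loss (scale 0.5 mm ≈ one pixel of edge-localisation noise).
Default bounds are ±25° / ±20 mm around the initial guess. When several
components share one image, each edge pixel is assigned to the component
whose expected outline lies nearest (within 10 mm), so one component's
edges stay out of a neighbour's target even where the silhouettes nearly
touch.

A fit is **suspect** when its residual exceeds 2 pixels, and a case is
additionally flagged by the **view-consistency check**: each view rescans
the axial rotation on its own; preferences disagreeing by >4° with >0.03 mm
cost improvement on at least one side indicate a pair no single rigid pose
can explain — the signature of the foot moving between the two exposures.
Those two thresholds were calibrated on noise-free synthetic matched pairs
(disagreement ≤2.4°, improvements ≤0.024 mm) versus 10°-twisted pairs
(disagreement ≥3.9°, improvements ≥0.034 mm).

## Tibial axis

* **2D (radiographic)**: a circle is fitted to shaft-outline points in a
  proximal and a distal band (Pratt's algebraic least-squares fit, centred
  and scaled for conditioning — deterministic, replacing the interactive
  circle alignment); the axis is the line through the two centres. The
  shaft span used is recorded, because too-distal radiographs constrain
  the axis poorly.
* **3D (gold standard)**: a segmented tibia mesh is cut by 20 equally
  spaced planes across the central 60 % of the shaft (avoiding the
  metaphyseal flare; both defaults are package choices, as no standard
  count exists), and a total-least-squares line is fitted through the
  cross-section area centroids. Accuracy of a radiographic measurement is
  `(1 − |V_A − V_O|/|V_A|)·100 %` against the 3D-derived value `V_A`;
  negative values are retained, since clamping would silently bias means.

## Statistics

Observer agreement uses ICC(2,1) — two-way random effects, absolute
agreement, single measures — computed from the two-way ANOVA mean squares
and cross-checked against `pingouin`; ICC(3,1) and ICC(2,k) are available
for sensitivity analysis. Method comparison uses two-sided paired t-tests
(identical vectors → t=0, p=1; a constant non-zero shift is returned as an
infinite statistic flagged degenerate). No multiple-testing correction is
applied; each parameter carries its own p-value. Observer summary tables
report per-observer mean ± SD and Δ = |difference of observer means|.

## Synthetic ground truth

Real radiographs never come with a known pose, so validation runs on a
parametric world:

* **Tibial tray**: elliptic plateau (30×25 mm footprint, 4 mm thick) with
  a 38 mm fixation stem and a short anterior peg. In the asymmetric
  configuration the stem is oblique (30° medially, 12° anteriorly), which
  removes every mirror plane; the peg exists because without it rotation
  about the oblique stem's own axis is a near-invariant soft mode (the
  elliptic plate is almost a body of revolution) and axial rotation would
  be practically unidentifiable — real trays carry pegs/keels for the
  analogous mechanical reason.
* **Talar dome**: a smooth convex profile (superior circular arc of radius
  11 mm, gently convex inferior arc) extruded 26 mm medial-laterally, plus
  an inferior fin. Smoothness keeps foreshortening rotations second-order
  in the silhouette; the flat medial/lateral end caps are what make axial
  rotation observable.
* **Tibia shaft**: tapered tube (radii 14→11 mm, length 200 mm) with
  exact analytic centreline, optional tilt, seeded surface roughness and
  sinusoidal radius modulation (which leaves the centroid locus on the
  centreline by construction).
* **Images**: silhouette-only renders (implant dark on light background)
  — the matching principle uses contours only, so attenuation realism adds
  nothing testable. Rendering is anti-aliased (4× supersampled occupancy,
  average-pooled): a real detector integrates flux over each pixel, so
  boundary pixels take intermediate grey values that carry sub-pixel edge
  position; a binary mask would quantise the contour evidence at the
  pixel grid and place a ~0.15 mm floor under every edge-based result. Degradations: Gaussian blur (σ in px), additive
  Gaussian noise (fraction of dynamic range), and occlusion as *feathered
  local contrast washout* in discs along the boundary. The washout model
  was chosen over opaque patches deliberately: an opaque patch fabricates
  sharp rim edges that no edge detector can distinguish from implant
  edges, turning an occlusion experiment into a clutter experiment;
  washing out contrast removes contour evidence the way an overlying
  structure of similar opacity does. The default placement puts the talar
  dome 6 mm below the tray — the radiolucent polyethylene liner — so the
  two silhouettes do not interpenetrate. All randomness flows from the
  single case seed; identical seeds give bit-identical images.
* **Movement artifact**: the lateral view is rendered after an extra
  rotation about the longitudinal axis (default 10°) — the simplest rigid
  model of the foot moving between exposures, making the pair inconsistent.

What passing tests on this world do **not** show: robustness to real
radiographic texture (bone trabeculae, soft tissue, scatter), to beam
divergence, or to the silhouette complexity of any commercial implant —
the stand-in geometry makes no fidelity claim, and quantitative robustness
numbers do not transfer.

## Problem sizes and numerical choices

The validation harness uses 50 random poses (rotations ±10°, translations
±5 mm, the clinically relevant malalignment envelope) for noise-free
recovery, 20 poses for the degraded condition (blur σ=1 px, 5 % noise,
20 % occlusion), 20 seeded matched/twisted case pairs for artifact
detection, exhaustive 0.25° grids per rotation axis for the uniqueness
check, and 1000-replicate Monte Carlo for the t-test power comparison.
Contour sampling is 0.5 mm; least-squares refinement uses 192 model
boundary samples per view, relative finite-difference step 1e-3, and stops
at `xtol = 1e-6`. Degenerate inputs (edge-on projections, collinear circle
points, constant rating matrices, zero reference values) raise explicit
errors rather than returning silently wrong numbers.

## Known limitations

* Orthographic projection ignores magnification; absolute translations are
  only as good as the supplied pixel spacing.
* The view-consistency check targets rotation about the longitudinal axis
  (the dominant foot-movement mode); a pure inter-view translation along
  the shared axis would not be caught.
* Single-view fits are intentionally under-determined; results from one
  view are only used diagnostically.
* Components whose silhouettes overlap in a view lose the shared boundary
  evidence; the fitter degrades gracefully but accuracy claims hold for
  non-overlapping (liner-separated) configurations.
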