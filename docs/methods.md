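# Methods

`vesselprox` measures the spatial relationship between a segmented tumor and
an adjacent vessel — the motivating case is a tonsillar tumor and the
internal carotid artery (ICA), where the minimum tumor-to-artery distance
(dTICA) informs candidacy for transoral robotic surgery. The package
consumes segmentation label maps only; it does not segment images.

## Coordinate conventions

All world coordinates are millimetres in the LPS (left-posterior-superior)
frame, the native frame of ITK. NIfTI files, whose on-disk affine is RAS,
are converted on read by SimpleITK; NRRD metadata is already LPS. Voxel
indices are 0-based and address voxel *centers*:
`world = origin + direction @ (spacing * index)`. This matches the vertex
placement of marching cubes, so iso-surface vertices and voxel-derived
world coordinates live in the same frame without half-voxel offsets.
Volumes with rotated (non-axis-aligned) direction matrices are accepted
everywhere except slice-wise centerline extraction, which resamples them to
an axis-aligned grid (nearest-neighbor on labels, geometry moves at most
half a voxel) when the slicing axis is more than 10 degrees from the world
superior axis.

## Surface extraction

Meshes are extracted by marching cubes at the fixed 0.5 iso-level of the
binary mask, with linear-interpolated vertex placement, after one voxel of
zero padding (so structures touching the grid edge still close). Smoothing
is OFF by default: the raw iso-surface is deterministic and keeps phantom
distances reproducible. Taubin smoothing (volume-preserving, shrink-free)
is available per call.

One consequence matters for morphometry: the raw binary iso-surface carries
a staircase *area* bias that does not vanish with resolution (measured
+8.5% at 1 mm and +9.3% at 0.5 mm spacing on an r = 10 mm sphere). Distances
and volumes are essentially unaffected — the surface stays within half a
voxel of the true boundary — but summed triangle area systematically
overestimates. `tumor_metrics` therefore measures surface area on a
Taubin-smoothed copy (10 iterations; residual error ~2%, vertex movement
< 0.2 mm on the test sphere), while distance measurements keep the raw
surface.

## Distance field, dTICA and MDP

For every vertex of the source mesh (the vessel, which carries the heatmap)
the minimum Euclidean distance to the target mesh (the tumor) is computed.
Two correspondence modes exist:

- `vertex-to-vertex` — distance to the nearest target vertex, the plain
  point-cloud form `v = sqrt((x1-x2)^2 + (y1-y2)^2 + (z1-z2)^2)`;
- `vertex-to-surface` (default) — distance to the nearest point on any
  target triangle. It is never larger than the vertex mode and strictly
  more accurate for coarse meshes.

Queries are accelerated with two k-d trees (target vertices for an upper
bound, triangle centroids for candidate pruning) but remain exact: any
triangle whose closest point could beat the per-vertex upper bound has its
centroid within `bound + max triangle circumradius` of the query, so the
candidate set provably contains the optimum. Tests compare against an
exhaustive all-pairs / all-triangles scan.

dTICA is the minimum of the field; the minimum distance point (MDP) is the
source vertex attaining it. Ties within 1e-9 mm resolve to the lowest
vertex index (deterministic), with all tied indices retained. When the
vessel mesh has several face-connected components (bilateral arteries) the
field covers all vertices and per-component minima are reported next to
the global minimum. Touching or overlapping structures clamp at 0 mm with
a warning — penetration depth is out of scope.

## Centerline and MDP arc position

Following the slice-marching construction, each transverse slice's
centerline node is the point equally distant from the vessel wall: the
centroid of the argmax set of the in-slice 2D Euclidean distance transform
(spacing-aware; the centroid rule breaks plateau ties deterministically).
Nodes are ordered inferior to superior and smoothed with a 3-point moving
average (default ON — staircase jitter otherwise inflates arc length;
disable with `smooth=False`). Empty slices inside the span are skipped
with a warning; more than 3 consecutive missing slices is treated as a
broken segmentation and raises.

The carotid-bifurcation end anchors arc length. By convention it is the
inferior endpoint (segmentations run from the bifurcation up to the
mandibular condyle); an optional fiducial point overrides the choice, and
a fiducial farther than 20 mm from both endpoints is rejected as a probable
wrong-side marking. The MDP's position is the cumulative arc length of its
nearest centerline node. This is a single-vessel construction: it does not
detect the bifurcation on a full carotid tree.

## Morphometry

- Volume: foreground voxel count x voxel volume. A divergence-theorem mesh
  volume is provided as an independent cross-check (agreement within 5% on
  phantoms at <= 1 mm spacing).
- Surface area: summed triangle area of the smoothed surface (see above).
- Transverse diameter TD: the bounding box is axis-aligned in world
  (patient) axes — not an oriented minimal box, since TD is defined in the
  transverse plane of the box and must stay coupled to the anatomical
  axes — and `TD = sqrt(dx^2 + dy^2)` over the two transverse extents.
  Volume-based extents use the voxel footprint (span of centers plus one
  voxel per axis), which equals the 0.5 iso-surface extent exactly for
  axis-aligned solids.

## Segmentation evaluation

DSC is volumetric: `2|A n B| / (|A| + |B|)` on a shared grid; grids that
differ beyond 1e-6 metadata jitter are a hard error (no silent resampling).
AHD is the mean distance from each reference surface vertex to its closest
point on the predicted surface; directed (reference -> prediction) by
default per the ground-truth-anchored definition, with the symmetric mean
of both directions exposed. Both masks empty is undefined and raises.

## Phantoms and ground truth

Phantoms pair a tubular vessel with a spherical tumor on a controllable
grid (default 96^3 at 1 mm — a desk-scale stand-in for clinical head CT at
512x512 with 1 mm slices). Truth values come from the continuous geometry,
never the rasterized voxels:

- straight tubes are flat-capped cylinders; clearance is the exact
  point-to-capped-cylinder surface distance minus the tumor radius (the
  closest approach may be the lateral wall, a flat cap, or the cap rim);
- arc tubes (circular arc in the x-z plane) measure clearance as
  distance-to-curve minus tube radius, minimized numerically to 1e-9; the
  tube is cut flat at its z-range, so validation restricts arc phantoms to
  lateral closest approach where that formula is exact;
- MDP arc position is the analytic arc length from the inferior end to the
  closest-approach parameter; tumor volume/area/TD are closed forms.

The staged cohort generator emulates a 4-stage (T1-T4) design with
n = 15 cases per stage by default. Per-stage mean tumor-vessel separations
default to (9.76, 7.49, 4.75, 4.80) mm — the clinically observed trend of
higher-stage tumors lying closer to the artery — with truncated-normal
noise (sd 2 mm, floor 0.5 mm). Stage tumor radii (10.1, 11.0, 16.8,
18.6 mm) reproduce the reported per-stage mean tumor volumes of roughly
4.3, 5.6, 19.9 and 27.1 cm^3, with 0.5 mm jitter. Tumor height along the
vessel is uniform. A single seeded generator drives every draw, so cohorts
are bit-reproducible.

What phantoms do not emulate: CT intensities and artifacts, segmentation
error (phantom masks are perfect rasterizations), anatomically curved
carotid trees with real bifurcations, non-spherical tumor shapes, and
partial-volume effects. Passing tests therefore demonstrate the geometry
and statistics of the *measurement* pipeline, not robustness to imperfect
segmentations — on real data the upstream segmentation quality dominates
(which is what the DSC/AHD module quantifies).

## Statistics

Cohort comparisons use one-way fixed-effects ANOVA per measure across
stages, pairwise two-sided equal-variance t-tests (uncorrected by default,
matching common practice in this setting; a Holm step-down flag is
available and documented as the conservative choice), and Pearson r /
R^2 of each measure against dTICA. The automatic-vs-manual comparison is a
two-sided paired t-test on equal-length readings. Alpha is 0.05 by
convention; the package reports p-values, it does not threshold them.

## Numerical choices and problem sizes

- MDP tie tolerance 1e-9 mm; distance queries exact (no approximation
  tolerance).
- Mesh component ordering: descending vertex count, then ascending
  centroid x — deterministic outputs.
- Degenerate inputs raise early with the offending stage named
  (`PipelineError` carries case id + stage).
- Tests and the acceptance script use phantoms between 48^3 and 96^3 at
  2 / 1 / 0.5 mm spacing and a 60-case full-pipeline cohort; these sizes
  keep the whole suite in the tens of seconds while leaving discretization
  error (about one voxel diagonal for distances, a few percent for
  volume/area) clearly measurable against the analytic truths.

## Known limitations

- Arc-length localization uses nearest-node projection, quantized to slice
  spacing; sub-slice interpolation is not attempted.
- The slice-wise centerline assumes a near-vertical vessel; highly tortuous
  or horizontal segments would need a 3D minimal-path formulation.
- No penetration depth for overlapping structures (clamped at 0 mm).
- DSC/AHD require identical grids; cross-scanner comparisons must resample
  explicitly beforehand.
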