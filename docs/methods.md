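# Methods

## Problem

Leaf pruning of greenhouse sweet pepper removes the lowest leaves by cutting
their petioles close to the stem. A pruning robot needs that cut location in
3D, relative to its camera. `pepperprune` computes it from a sequence of
per-frame inputs an upstream perception stack provides: a semantic label
image (pixel codes 0 other, 1 stem, 2 petiole, 3 leaf, 4 fruit, produced by
a segmentation network that is *not* part of this package), the aligned
depth image, and the camera pose (produced by a visual-SLAM system, also not
part of this package).

## Pipeline

**1. 2D pruning regions (`semantic2d`).** Stem and petiole indicator layers
are extracted from the label raster and denoised by dropping 8-connected
components below `min_area_2d` pixels (default 50 at 640×480, scaled by
raster area; denoising happens once, before any dilation). Both layers are
dilated with a centered all-ones `kernel_size`×`kernel_size` kernel
(default 7×7, windows clipped at borders); their intersection marks petiole
root points — evidence that a petiole touches the stem in image space. That
intersection is dilated again and intersected with the *original* denoised
petiole layer; each 8-connected component of the result is a pruning
region, and the member pixel nearest the region centroid is its 2D pruning
point (the nearest-member rule keeps the point on petiole tissue even for
curved regions).

**2. Semantic clouds (`cloud`).** Detected regions are painted into the
label raster as code 5, and every plant-labeled pixel (codes 1–5) with a
valid depth measurement is unprojected through the pinhole model
(z = depth/scaling_factor, x = (u−cx)·z/f, y = (v−cy)·z/f). All internal
coordinates are millimeters; `scaling_factor` is depth-raster units per mm
(1 for a RealSense-style depth-in-mm stream). Points beyond `max_depth_mm`
(default 1500, the camera standing ~1 m from the plant) are discarded, and
pixels with depth 0 are treated as missing. Clouds are voxel-downsampled at
resolution `r` (default 1 mm); each occupied voxel keeps the centroid of
its points with the majority label (ties toward the smaller code), which is
order-independent because centroids are accumulated in double precision.

**3. Registration (`register`).** Per-frame clouds are placed in the world
frame by the SLAM pose and refined by point-to-point ICP against the
accumulated cloud (frame-to-model; a frame-to-frame switch exists). ICP is
seeded with the previous *refined* pose composed with the raw SLAM pose
delta, so only residual drift must be estimated. The inner step is the
closed-form SVD/Kabsch fit with reflection correction; correspondences are
nearest neighbors within `30 × r` mm (kd-tree), iterating at most 50 times
until the rms residual changes by (or falls below) 0.01 mm. Correspondence
search ignores semantic labels by default; `match_labels` restricts
matching to same-label pairs. If no correspondence exists within the
capture radius the frame is dropped with a warning and accumulation
continues.

**4. 3D pruning point (`prune3d`).** Pruning-labeled points (code 5) are
grouped by Euclidean cluster extraction with inclusive threshold
`t = 1.5 × r`: seeded stack expansion over kd-tree radius queries,
equivalent to connected components of the ≤ t proximity graph. Seeds are
taken in ascending index order purely for reproducibility — the partition
itself is seed-invariant. Clusters whose closest points lie within
`merge_dist` (default `5 × r`, larger than t so cross-viewpoint patches of
one petiole merge while distinct petioles centimeters apart do not) are
unioned transitively; clusters below `min_cluster_size` points (default 10)
are dropped as noise. Among the survivors, the cluster whose centroid is
extremal along the vertical axis (default: minimal y) marks the lowest
petiole; its centroid is the reported pruning point. Ties go to the larger
cluster, then the lower enumeration index.

**5. Orchestration (`pipeline`).** The live multi-process loop of a robot
deployment is replaced by a frame manifest (CSV) plus a TUM-format
trajectory file (`timestamp tx ty tz qx qy qz qw`, translation meters →
mm, Hamilton quaternion w-last). Statistical outlier removal (mean k-NN
distance > global mean + `std_mult`·std, defaults k=20, std_mult=2) runs
once on the accumulated cloud before the 3D search; it is a config toggle.
The result is a JSON report `{x_mm, y_mm, z_mm, cluster_size,
n_clusters_considered, …}` and optionally a palette-colored PLY.

## Vertical axis

The selection rule "smallest y is lowest" matches a y-up world frame. The
synthetic world is therefore y-up (stem along +y); the camera convention is
x-right/y-down/z-forward, and the look-at constructor maps image rows to
world −y. For real SLAM trajectories whose world frame is the first camera
frame (y-down), set `direction: max` — both axis and direction are config
fields because the convention cannot be fixed for every SLAM setup.

## Synthetic world (`synthetic`)

A plant is a vertical stem capsule (radius 6 mm, height 400 mm) with
petiole capsules (radius 2 mm, length 90 mm) attached at distinct heights
≥ `spacing_mm` apart, each ending in a leaf disc (radius 35 mm) that can
occlude other parts. Petioles tilt 5–25° above horizontal (pruning-age
lower leaves droop toward horizontal) and take azimuths within a ±50°
sector about the lateral (±x) axes, alternating sides. The sector models
the capture protocol — an operator films the plant from a side where stem
and petioles are visible — and reflects a genuine limitation of the 2D
detection: a petiole aligned with the camera's depth axis appears
near-vertical in the image, hugs the stem silhouette for tens of mm, and
its painted pruning region smears along the (image-invisible) depth
direction. The ±50° bound comes from the geometric requirement that the
in-image petiole inclination stays shallow enough
(atan(tan tilt / cos azimuth) ≲ 30°) for the painted patch to remain a few
pixels long.

Frames are rendered by sampling primitive surfaces on deterministic grids
(spacing = half the pixel footprint at the 400 mm nearest working distance,
≥ 4 samples per pixel), projecting through the pinhole model (f = 525 px,
640×480, depth units of 1 mm), and resolving occlusion with a painter's
z-buffer. Noise knobs: Gaussian depth noise (`depth_sigma_mm`), depth
dropout (depth → 0 with `dropout_prob`), and camera translation jitter
(`pose_jitter_mm`) applied to the *rendering* pose while the reported pose
stays nominal — emulating SLAM pose error and breeze-shaken plants. The
default trajectory arcs (up / left / right / mix, 100 mm extent, ~550 mm
standoff) start and stop at the same pose.

The generator does **not** emulate: segmentation errors (mislabeled
pixels), leaf blade deformation, stems that bend or branch, fruit, or
depth-sensor artifacts beyond Gaussian noise and dropout. A green
end-to-end test therefore establishes geometric correctness of the
pipeline, not robustness to perception failures.

Per-petiole ground truth is the petiole-axis point where the capsule exits
the stem surface — the cut position "close to the stem".

## Numerical choices

- Distance thresholds (cluster t, merge radius, ICP capture radius) are
  inclusive (≤).
- Dilation windows clip at image borders; no wraparound.
- Pixels are 0-indexed, u = column, v = row, pixel centers at integers.
- Rotation matrices are validated to ‖RᵀR−I‖∞ < 1e−6 and det ≈ +1; the
  best-fit solver rejects < 3 pairs or near-collinear configurations
  (second singular value < 1e−9 of the first).
- ICP declares convergence when the rms residual is below
  `convergence_delta` *before* taking a step, so already-aligned clouds
  return the initial transform exactly.
- Voxel keys are `floor(p / r)`; points exactly on voxel boundaries follow
  floor semantics deterministically.

## Known limitations

- The reported point is the centroid of the painted petiole patch. The
  true stem-surface attachment is always at the *edge* of that patch
  (petiole pixels exist only outboard of the stem silhouette), so the
  estimate carries a one-sided outward bias of roughly half the patch
  length — a few mm for side-on petioles, growing with in-image petiole
  steepness. The ground-truth-recovery acceptance test runs directly at
  this bias level and can sit near its 5 mm bound; the multi-trajectory
  stability checks are insensitive to the bias because it is common to all
  trajectories of a plant.
- A petiole pointing at (or away from) the camera cannot be localized from
  that viewpoint (see the azimuth-sector rationale above); real deployments
  rely on the camera arc providing side views.
- 2D junction detection is purely image-space: a petiole passing in front
  of or behind the stem can create a spurious junction at a different
  depth. Cluster size filtering and multi-view accumulation suppress, but
  do not eliminate, such artifacts.
- Frame-to-model ICP assumes the first frame's pose is trustworthy; there
  is no loop closure (the capture path does not loop).
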